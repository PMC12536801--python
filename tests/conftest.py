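import numpy as np
import pytest

from spomag import (
    CVConfig,
    FeatureMatrix,
    GeneCatalog,
    GeneCatalogEntry,
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    SimulationConfig,
    default_catalog,
    simulate_matrix,
    stratified_partition,
    train_spomag,
)


@pytest.fixture(scope="session")
def catalog160():
    return default_catalog()


@pytest.fixture(scope="session")
def small_catalog():
    """Eight-gene catalog spanning several stages, with aliases and KOs."""
    entries = (
        GeneCatalogEntry("spoVD", frozenset({"K08384"}), frozenset({"pbpB2"}),
                         "spore cortex"),
        GeneCatalogEntry("spo0A", frozenset({"K07699"}), frozenset(),
                         "Spo0A regulon"),
        GeneCatalogEntry("gerD", frozenset({"K06295"}), frozenset(),
                         "germination"),
        GeneCatalogEntry("cotP", frozenset(), frozenset({"cotP1"}),
                         "spore coat"),
        GeneCatalogEntry("spoIIR", frozenset({"K06382"}), frozenset(),
                         "SigF regulon"),
        GeneCatalogEntry("sigE", frozenset({"K03092"}), frozenset(),
                         "SigE regulon"),
        GeneCatalogEntry("pth", frozenset({"K01056"}), frozenset(),
                         "sporulation onset and checkpoints"),
        GeneCatalogEntry("ftsW", frozenset({"K03588"}), frozenset(),
                         "engulfment"),
    )
    return GeneCatalog(entries=entries, version_tag="test-8")


def make_matrix(values, labels=None, checksum="", gene_prefix="f"):
    """Helper: FeatureMatrix from a 2D array with generated ids."""
    values = np.asarray(values, dtype=np.uint8)
    n, d = values.shape
    ids = [f"g{i:03d}" for i in range(n)]
    lab = None
    if labels is not None:
        lab = {
            ids[i]: (POSITIVE_LABEL if labels[i] else NEGATIVE_LABEL)
            for i in range(n)
        }
    return FeatureMatrix(
        genome_ids=ids,
        gene_symbols=[f"{gene_prefix}{j:03d}" for j in range(d)],
        values=values,
        labels=lab,
        catalog_checksum=checksum,
    )


@pytest.fixture(scope="session")
def planted_small(catalog160):
    """Small, strongly separable cohort for fast ensemble tests."""
    cfg = SimulationConfig(
        n_sporulating=20, n_nonsporulating=20, n_informative=20, seed=42
    )
    matrix, truth = simulate_matrix(cfg, catalog160)
    return matrix, truth


@pytest.fixture(scope="session")
def small_bundle(planted_small):
    """SpoMAG bundle trained once on the small planted cohort's 70% split."""
    matrix, _ = planted_small
    train_ids, test_ids = stratified_partition(matrix.labels, 0.7, seed=7)
    bundle = train_spomag(matrix.subset(train_ids), CVConfig(seed=7))
    return bundle, matrix.subset(train_ids), matrix.subset(test_ids)
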