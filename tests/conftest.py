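import pytest

import premirdist as pm


@pytest.fixture(scope="session")
def tiny_catalog() -> pm.Catalog:
    """Four short fixed hairpins for brute-force pairwise checks."""
    return pm.Catalog(
        [
            pm.HairpinRecord("syn-mir-0001", "t1", "ACGUACGUACGUACGU"),
            pm.HairpinRecord("syn-mir-0002", "t2", "ACGUACGUACGUACGA"),
            pm.HairpinRecord("syn-mir-0003", "t3", "UGCAUGCAUGCAUGCA"),
            pm.HairpinRecord("syn-mir-0004", "t4", "ACGUACGUAAAAACGU"),
        ]
    )


@pytest.fixture(scope="session")
def resolution_catalog() -> pm.Catalog:
    """Catalog with multi-locus and arm-letter name collisions."""
    seqs = pm.generate_fixture_catalog(8, (60, 60), seed=42).records
    ids = [
        "hsa-let-7a-1", "hsa-let-7a-2", "hsa-let-7a-3",
        "hsa-mir-21", "hsa-mir-323a", "hsa-mir-323b",
        "hsa-mir-100", "hsa-mir-1003",
    ]
    return pm.Catalog(
        pm.HairpinRecord(i, i, r.sequence) for i, r in zip(ids, seqs)
    )


@pytest.fixture(scope="session")
def study_distances() -> pm.CondensedDistances:
    """All-pairs distances of the standard synthetic study catalog."""
    return pm.pairwise_distances(pm.study_catalog(), progress_every=0)
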