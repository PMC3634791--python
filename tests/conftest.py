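import numpy as np
import pandas as pd
import pytest

from vertfine.config import RunConfig
from vertfine.markers import MarkerMap
from vertfine.pedigree import Pedigree
from vertfine.genotypes import PhasedGenotypeMatrix


@pytest.fixture
def small_map() -> MarkerMap:
    """Ten evenly spaced markers on one chromosome (1 Mb = 1 cM)."""
    return MarkerMap.from_positions(
        [f"m{i}" for i in range(10)],
        ["7"] * 10,
        [int(1e6 * (i + 1)) for i in range(10)],
    )


@pytest.fixture
def trio_pedigree() -> Pedigree:
    return Pedigree.from_records(
        [
            ("sire", None, None, "M", "F0", "P"),
            ("dam", None, None, "F", "F0", "P"),
            ("kid", "sire", "dam", "M", "F1", "P"),
        ]
    )


def matrix_from_haplotypes(haps: dict[str, tuple[list[int], list[int]]], mm: MarkerMap):
    """Build a phased matrix from {id: (hap0, hap1)} allele lists."""
    ids = list(haps)
    a = np.stack(
        [np.stack([haps[i][0], haps[i][1]], axis=1) for i in ids]
    ).astype(np.int8)
    return PhasedGenotypeMatrix(ids=ids, markers=mm, alleles=a)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run on the three-population synthetic study."""
    from vertfine.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("demo_run")
    cfg = RunConfig(seed=7, out_dir=str(out))
    report = run_pipeline(cfg)
    return cfg, report


@pytest.fixture(scope="session")
def demo_fixture():
    from vertfine.designs import build_fixture

    return build_fixture(seed=11)
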