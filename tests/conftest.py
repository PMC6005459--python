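import numpy as np
import pandas as pd
import pytest

from wtprofiler import synthetic
from wtprofiler.baf import SnpSite
from wtprofiler.bisulfite import AmpliconRef
from wtprofiler.expression import ExpressionMatrix, MarkerGeneSet


@pytest.fixture(scope="session")
def amplicon() -> AmpliconRef:
    """Synthetic GC-rich CpG-island amplicon (23 CpGs over 253 bp)."""
    return synthetic.make_amplicon()


@pytest.fixture
def tiny_amplicon() -> AmpliconRef:
    return AmpliconRef(name="tiny", sequence="TACGGATCGCAT")


def make_sites(n: int = 50, seed: int = 0) -> list[SnpSite]:
    """Random site list (sorted) spanning the filter boundaries."""
    rng = np.random.default_rng(seed)
    sites = []
    pos = 0
    for i in range(n):
        pos += int(rng.integers(1, 1000))
        sites.append(SnpSite(
            chrom="chr1",
            pos=pos,
            normal_genotype=str(rng.choice(["0/1", "0/0", "1/1", "0|1"])),
            normal_depth=int(rng.integers(0, 1200)),
            tumour_ref_depth=int(rng.integers(0, 700)),
            tumour_alt_depth=int(rng.integers(0, 700)),
            genotype_quality=float(rng.integers(0, 100)),
        ))
    return sites


@pytest.fixture
def random_sites() -> list[SnpSite]:
    return make_sites()


def make_expression(n_probes: int = 40, n_a: int = 5, n_b: int = 5,
                    seed: int = 0, shift_first: int = 0,
                    shift: float = 0.0) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    vals = 7.0 + rng.standard_normal((n_probes, n_a + n_b))
    if shift_first:
        vals[:shift_first, :n_a] += shift
    probes = [f"P{i:05d}" for i in range(n_probes)]
    samples = [f"A{j}" for j in range(n_a)] + [f"B{j}" for j in range(n_b)]
    groups = pd.Series(["a"] * n_a + ["b"] * n_b, index=samples)
    return ExpressionMatrix(values=pd.DataFrame(vals, index=probes, columns=samples),
                            sample_groups=groups)


@pytest.fixture
def expr_matrix() -> ExpressionMatrix:
    return make_expression()


@pytest.fixture
def marker_set() -> MarkerGeneSet:
    return MarkerGeneSet("stage_early", tuple(f"P{i:05d}" for i in range(10)))
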