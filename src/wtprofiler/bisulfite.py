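"""Targeted bisulfite-amplicon methylation analysis.

Calls per-read, per-CpG methylation from position-fixed amplicon reads,
summarises per-CpG methylation proportions, classifies reads into epialleles
(densely methylated vs unmethylated vs intermediate), estimates mutation
allele fractions by local-context counting, and converts an allele-level
fraction into a mosaic cell fraction under the one-methylated-allele-per-cell
model.

Conventions: all CpG coordinates are 0-based offsets of the CpG cytosine on
the top strand.  Bottom-strand reads are represented in top-strand
orientation, so bisulfite conversion on that strand appears as G→A changes
and the informative base for a CpG is the guanine at offset + 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

#: ternary call codes used in :class:`MethylationCallMatrix.calls`
CALL_METHYLATED = 1
CALL_UNMETHYLATED = 0
CALL_MISSING = -1

_LOLLIPOP_SYMBOL = {CALL_METHYLATED: "M", CALL_UNMETHYLATED: "U", CALL_MISSING: "."}
_LOLLIPOP_CODE = {v: k for k, v in _LOLLIPOP_SYMBOL.items()}


def detect_cpg_positions(sequence: str) -> list[int]:
    """Return 0-based offsets of every CpG cytosine (top strand)."""
    seq = sequence.upper()
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


@dataclass(frozen=True)
class AmpliconRef:
    """A targeted amplicon reference with annotated CpG sites.

    Parameters
    ----------
    name : str
        Amplicon identifier.
    sequence : str
        Top-strand DNA sequence.
    cpg_positions : sequence of int
        0-based offsets of CpG cytosines on the top strand.  If omitted,
        detected from the sequence.
    genomic_anchor : (str, int), optional
        Chromosome and 1-based start used only for reporting.
    """

    name: str
    sequence: str
    cpg_positions: tuple[int, ...] = ()
    genomic_anchor: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not self.cpg_positions:
            object.__setattr__(self, "cpg_positions", tuple(detect_cpg_positions(seq)))
        else:
            object.__setattr__(self, "cpg_positions", tuple(int(p) for p in self.cpg_positions))
        for p in self.cpg_positions:
            if p < 0 or p + 1 >= len(seq) or seq[p] != "C" or seq[p + 1] != "G":
                raise ValueError(f"cpg_position {p} does not index a CpG in {self.name}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BisulfiteTemplates:
    """The four expected post-conversion templates of an amplicon.

    All four are in top-strand orientation.  Top-strand conversion turns
    every non-CpG C into T and leaves CpG cytosines as C (methylated) or T
    (unmethylated); the bottom strand is symmetric with G→A, its CpG-informative
    base being the G at ``cpg + 1``.
    """

    top_methylated: str
    top_unmethylated: str
    bottom_methylated: str
    bottom_unmethylated: str

    def as_dict(self) -> dict[tuple[str, bool], str]:
        return {
            ("top", True): self.top_methylated,
            ("top", False): self.top_unmethylated,
            ("bottom", True): self.bottom_methylated,
            ("bottom", False): self.bottom_unmethylated,
        }


def convert_reference(ref: AmpliconRef) -> BisulfiteTemplates:
    """Build the four expected bisulfite-converted templates for *ref*."""
    seq = np.frombuffer(ref.sequence.encode(), dtype="S1").copy()
    cpg = np.asarray(ref.cpg_positions, dtype=int)
    cpg_g = cpg + 1

    top_meth = seq.copy()
    is_c = top_meth == b"C"
    conv = is_c.copy()
    conv[cpg] = False  # methylated CpG C retained
    top_meth[conv] = b"T"

    top_unmeth = seq.copy()
    top_unmeth[is_c] = b"T"

    bottom_meth = seq.copy()
    is_g = bottom_meth == b"G"
    conv = is_g.copy()
    conv[cpg_g] = False
    bottom_meth[conv] = b"A"

    bottom_unmeth = seq.copy()
    bottom_unmeth[is_g] = b"A"

    return BisulfiteTemplates(
        top_methylated=top_meth.tobytes().decode(),
        top_unmethylated=top_unmeth.tobytes().decode(),
        bottom_methylated=bottom_meth.tobytes().decode(),
        bottom_unmethylated=bottom_unmeth.tobytes().decode(),
    )


@dataclass
class MethylationCallMatrix:
    """Per-read, per-CpG ternary methylation calls.

    ``calls`` is an int8 array (reads × CpG sites) coded 1 = methylated,
    0 = unmethylated, -1 = missing.  ``conversion_failure_rate`` is the
    per-read fraction of non-CpG cytosine positions retained unconverted
    (C on top-strand reads, G on bottom-strand reads).
    """

    read_ids: list[str]
    cpg_sites: tuple[int, ...]
    calls: np.ndarray
    strand: np.ndarray  # unicode 'top'/'bottom' per read
    conversion_failure_rate: np.ndarray
    n_discarded: int = 0

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D reads x sites array")
        n, m = self.calls.shape
        if len(self.read_ids) != n or len(self.cpg_sites) != m:
            raise ValueError("inconsistent MethylationCallMatrix dimensions")
        self.strand = np.asarray(self.strand)
        self.conversion_failure_rate = np.asarray(self.conversion_failure_rate, dtype=float)
        if len(self.strand) != n or len(self.conversion_failure_rate) != n:
            raise ValueError("per-read annotations must match the number of reads")
        ok = np.isnan(self.conversion_failure_rate) | (
            (self.conversion_failure_rate >= 0) & (self.conversion_failure_rate <= 1)
        )
        if not ok.all():
            raise ValueError("conversion_failure_rate outside [0, 1]")

    @property
    def n_reads(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def methylated_fraction_per_read(self) -> np.ndarray:
        """Fraction of non-missing sites called methylated, NaN if none called."""
        called = (self.calls != CALL_MISSING).sum(axis=1)
        meth = (self.calls == CALL_METHYLATED).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, meth / np.maximum(called, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.calls, index=self.read_ids,
                          columns=[f"cpg_{p}" for p in self.cpg_sites])
        df.insert(0, "strand", self.strand)
        return df


@dataclass(frozen=True)
class EpialleleSummary:
    """Counts and dense-epiallele fraction with a Wilson 95% CI.

    ``n_reads`` counts the classified reads only (those with at least
    ``min_called`` non-missing calls); excluded reads are reported separately.
    """

    n_reads: int
    n_dense: int
    n_unmethylated: int
    n_intermediate: int
    n_excluded: int
    dense_fraction: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.n_dense + self.n_unmethylated + self.n_intermediate != self.n_reads:
            raise ValueError("epiallele counts must partition classified reads")

    @property
    def dense_percent(self) -> float:
        """Dense fraction as a percentage rounded to 1 decimal place."""
        return round(100.0 * self.dense_fraction, 1)

    def as_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_dense": self.n_dense,
            "n_unmethylated": self.n_unmethylated,
            "n_intermediate": self.n_intermediate,
            "n_excluded": self.n_excluded,
            "dense_fraction": self.dense_fraction,
            "dense_percent": self.dense_percent,
            "ci95": [self.ci_low, self.ci_high],
        }


def _reads_to_array(reads: Sequence[str], length: int) -> np.ndarray:
    """Stack reads into a (n, length) byte array, padding short reads with N."""
    arr = np.full((len(reads), length), b"N", dtype="S1")
    for i, r in enumerate(reads):
        r = r.upper()[:length]
        arr[i, : len(r)] = np.frombuffer(r.encode(), dtype="S1")
    return arr


def assign_and_call(
    reads: Sequence[str],
    ref: AmpliconRef,
    read_ids: Sequence[str] | None = None,
    min_identity: float = 0.8,
) -> MethylationCallMatrix:
    """Assign each read to a converted strand template and call CpG methylation.

    Reads are anchored at the amplicon start (position-fixed amplicon design,
    no gapped alignment).  Each read is compared against all four converted
    templates; the best-matching template fixes the strand.  Reads whose best
    identity falls below ``min_identity`` are discarded as off-target and
    counted in ``n_discarded``.

    Methylation at each CpG is read from the informative base: C (methylated)
    vs T (unmethylated) on top-strand reads, G vs A at ``cpg + 1`` on
    bottom-strand reads; any other base, or a site beyond the read end, is
    missing.  The per-read conversion failure rate is the retained fraction
    at non-CpG cytosine (top) or guanine (bottom) positions.
    """
    reads = list(reads)
    min_len = (len(ref) + 1) // 2
    for r in reads:
        if len(r) < min_len:
            raise ValueError("read shorter than half the amplicon length")
    if read_ids is None:
        read_ids = [f"read_{i}" for i in range(len(reads))]
    read_ids = list(read_ids)
    if len(read_ids) != len(reads):
        raise ValueError("read_ids length mismatch")

    L = len(ref)
    templates = convert_reference(ref)
    tmpl_names = [("top", True), ("top", False), ("bottom", True), ("bottom", False)]
    tmpl_arr = _reads_to_array([templates.as_dict()[k] for k in tmpl_names], L)

    arr = _reads_to_array(reads, L)
    covered = arr != b"N"
    n_cov = np.maximum(covered.sum(axis=1), 1)

    # identity of each read against each template over covered positions
    ident = np.empty((len(reads), 4))
    for t in range(4):
        ident[:, t] = ((arr == tmpl_arr[t]) & covered).sum(axis=1) / n_cov
    # a half-methylated read matches the two same-strand templates equally at
    # non-CpG positions; take the better of the pair per strand
    strand_ident = np.maximum(ident[:, 0::2], ident[:, 1::2])  # columns: top, bottom
    best_strand = np.argmax(strand_ident, axis=1)  # 0 = top, 1 = bottom
    best_ident = strand_ident[np.arange(len(reads)), best_strand]

    keep = best_ident >= min_identity
    n_discarded = int((~keep).sum())
    if n_discarded:
        logger.warning("assign_and_call: discarded %d off-target read(s) below identity %.2f",
                       n_discarded, min_identity)
    arr = arr[keep]
    best_strand = best_strand[keep]
    read_ids = [rid for rid, k in zip(read_ids, keep) if k]

    cpg = np.asarray(ref.cpg_positions, dtype=int)
    n, m = arr.shape[0], len(cpg)
    calls = np.full((n, m), CALL_MISSING, dtype=np.int8)
    conv_fail = np.full(n, np.nan)

    ref_arr = np.frombuffer(ref.sequence.encode(), dtype="S1")
    is_top = best_strand == 0
    # informative CpG base per strand
    for strand_mask, offs, meth_b, unmeth_b, nonconv_base, conv_base in (
        (is_top, cpg, b"C", b"T", b"C", b"T"),
        (~is_top, cpg + 1, b"G", b"A", b"G", b"A"),
    ):
        if not strand_mask.any():
            continue
        sub = arr[strand_mask][:, offs]
        c = np.full(sub.shape, CALL_MISSING, dtype=np.int8)
        c[sub == meth_b] = CALL_METHYLATED
        c[sub == unmeth_b] = CALL_UNMETHYLATED
        calls[strand_mask] = c
        # conversion failure over non-CpG C (top) / non-CpG G (bottom) positions
        nonconv_pos = np.flatnonzero(ref_arr == nonconv_base)
        nonconv_pos = nonconv_pos[~np.isin(nonconv_pos, offs)]
        sub2 = arr[strand_mask][:, nonconv_pos]
        retained = (sub2 == nonconv_base).sum(axis=1)
        converted = (sub2 == conv_base).sum(axis=1)
        denom = retained + converted
        cf = np.where(denom > 0, retained / np.maximum(denom, 1), np.nan)
        conv_fail[strand_mask] = cf

    strand = np.where(is_top, "top", "bottom")
    return MethylationCallMatrix(
        read_ids=read_ids,
        cpg_sites=ref.cpg_positions,
        calls=calls,
        strand=strand,
        conversion_failure_rate=conv_fail,
        n_discarded=n_discarded,
    )


def per_cpg_proportions(matrix: MethylationCallMatrix) -> pd.DataFrame:
    """Per-CpG methylated fraction with denominators, missing calls excluded.

    Sites with no informative call get fraction NaN and ``has_calls`` False.
    """
    meth = (matrix.calls == CALL_METHYLATED).sum(axis=0)
    unmeth = (matrix.calls == CALL_UNMETHYLATED).sum(axis=0)
    denom = meth + unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, meth / np.maximum(denom, 1), np.nan)
    return pd.DataFrame({
        "cpg_position": list(matrix.cpg_sites),
        "n_methylated": meth,
        "n_unmethylated": unmeth,
        "n_called": denom,
        "fraction_methylated": frac,
        "has_calls": denom > 0,
    })


def classify_epialleles(
    matrix: MethylationCallMatrix,
    dense_min: float = 0.9,
    unmeth_max: float = 0.1,
    min_called: int = 5,
) -> EpialleleSummary:
    """Classify reads into dense / unmethylated / intermediate epialleles.

    A read with at least ``min_called`` non-missing calls is *dense* if its
    methylated fraction is >= ``dense_min``, *unmethylated* if <= ``unmeth_max``
    and *intermediate* otherwise; reads with fewer calls are excluded from all
    denominators.  The dense fraction carries a Wilson 95% CI.
    """
    if matrix.n_reads == 0:
        raise ValueError("empty methylation call matrix")
    if not (0 <= unmeth_max < dense_min <= 1):
        raise ValueError("require 0 <= unmeth_max < dense_min <= 1")
    called = (matrix.calls != CALL_MISSING).sum(axis=1)
    frac = matrix.methylated_fraction_per_read()
    usable = called >= min_called
    n_excluded = int((~usable).sum())
    n_classified = int(usable.sum())
    if n_classified == 0:
        raise ValueError("all reads excluded by min_called")
    dense = usable & (frac >= dense_min)
    unmeth = usable & (frac <= unmeth_max)
    n_dense = int(dense.sum())
    n_unmeth = int(unmeth.sum())
    n_inter = n_classified - n_dense - n_unmeth
    lo, hi = proportion_confint(n_dense, n_classified, alpha=0.05, method="wilson")
    return EpialleleSummary(
        n_reads=n_classified,
        n_dense=n_dense,
        n_unmethylated=n_unmeth,
        n_intermediate=n_inter,
        n_excluded=n_excluded,
        dense_fraction=n_dense / n_classified,
        ci_low=float(lo),
        ci_high=float(hi),
    )


@dataclass(frozen=True)
class MutationLocus:
    """Local sequence context of a point mutation used for counting reads.

    ``ref_context`` and ``alt_context`` are short strings that uniquely anchor
    the locus in on-target reads (reference and mutant versions of the same
    window).
    """

    name: str
    ref_context: str
    alt_context: str

    def __post_init__(self) -> None:
        if not self.ref_context or not self.alt_context:
            raise ValueError("contexts must be non-empty")
        if self.ref_context == self.alt_context:
            raise ValueError("ref and alt contexts must differ")


@dataclass(frozen=True)
class MutationFractionResult:
    n_ref: int
    n_alt: int
    n_ambiguous: int
    fraction: float

    @property
    def percent(self) -> float:
        """Mutant allele fraction as a percentage rounded to 2 decimal places."""
        return round(100.0 * self.fraction, 2)


def mutation_allele_fraction(reads: Iterable[str], locus: MutationLocus) -> MutationFractionResult:
    """Count reads carrying the mutant vs reference local context.

    Reads matching neither context (or, pathologically, both) are excluded and
    counted as ambiguous.  If fewer than half the reads are anchorable the
    amplicon is presumed wrong and an error is raised.
    """
    n_ref = n_alt = n_amb = n_total = 0
    ref_c = locus.ref_context.upper()
    alt_c = locus.alt_context.upper()
    for r in reads:
        n_total += 1
        r = r.upper()
        has_ref = ref_c in r
        has_alt = alt_c in r
        if has_ref == has_alt:
            n_amb += 1
        elif has_alt:
            n_alt += 1
        else:
            n_ref += 1
    if n_total == 0:
        raise ValueError("no reads supplied")
    if (n_ref + n_alt) < 0.5 * n_total:
        raise ValueError(
            f"mutation context for {locus.name} anchored in only "
            f"{n_ref + n_alt} of {n_total} reads; wrong amplicon?"
        )
    return MutationFractionResult(
        n_ref=n_ref, n_alt=n_alt, n_ambiguous=n_amb,
        fraction=n_alt / (n_alt + n_ref),
    )


def estimate_cell_fraction(allele_fraction: float) -> float:
    """Convert a methylated-allele fraction into a mosaic cell fraction.

    Assumes each affected cell carries exactly one methylated allele among its
    two, so the cell fraction is twice the allele fraction.  Requires the
    allele fraction to be at most 0.5 (heterozygous-event assumption).
    """
    if not 0 <= allele_fraction <= 0.5:
        raise ValueError("allele_fraction must lie in [0, 0.5] under the "
                         "one-methylated-allele-per-cell model")
    return 2.0 * allele_fraction


def lollipop_matrix(matrix: MethylationCallMatrix) -> str:
    """Render the call matrix as a BiQ-style text grid (TSV).

    One row per read, densest reads first (ties broken by read id order);
    columns are CpG positions; symbols M / U / . for methylated /
    unmethylated / missing.  The rendering round-trips through
    :func:`parse_lollipop`.
    """
    header = ["read_id", "strand"] + [f"cpg_{p}" for p in matrix.cpg_sites]
    lines = ["\t".join(header)]
    frac = matrix.methylated_fraction_per_read()
    order = np.argsort(-np.nan_to_num(frac, nan=-1.0), kind="stable")
    for i in order:
        row = [matrix.read_ids[i], str(matrix.strand[i])]
        row += [_LOLLIPOP_SYMBOL[int(c)] for c in matrix.calls[i]]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def parse_lollipop(text: str) -> MethylationCallMatrix:
    """Parse a grid produced by :func:`lollipop_matrix` back into a matrix.

    Conversion-failure rates are not stored in the grid and come back as NaN.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    sites = tuple(int(c.removeprefix("cpg_")) for c in header[2:])
    read_ids, strands, rows = [], [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        read_ids.append(parts[0])
        strands.append(parts[1])
        rows.append([_LOLLIPOP_CODE[s] for s in parts[2:]])
    calls = (np.asarray(rows, dtype=np.int8) if rows
             else np.empty((0, len(sites)), dtype=np.int8))
    return MethylationCallMatrix(
        read_ids=read_ids,
        cpg_sites=sites,
        calls=calls,
        strand=np.asarray(strands),
        conversion_failure_rate=np.full(len(read_ids), np.nan),
    )
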