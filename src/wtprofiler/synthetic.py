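"""Truth-known synthetic inputs for every pipeline stage.

Three generators emulate the statistical structure the analyses assume:

* tumour/normal SNP allele-depth tracks with implanted copy-neutral-LOH,
  single-copy loss and single-copy gain segments at a given tumour purity;
* targeted bisulfite-amplicon reads drawn from a two-epiallele mixture
  (densely methylated vs unmethylated) with incomplete conversion and
  sequencing error, on both strands;
* log-scale expression matrices with subgroup structure and marker-gene
  shifts defining developmental-stage metagenes.

Every generator is bit-reproducible given its seed, and returns the truth
labels alongside the data so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bisulfite import AmpliconRef
from .expression import ExpressionMatrix, MarkerGeneSet

# tumour copy number per truth state (single-copy change model)
STATE_COPY_NUMBER = {"neutral_het": 2, "cn_loh": 2, "loss": 1, "gain": 3}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class CnvTruthSegment:
    """One implanted copy/LOH state segment (1-based, closed coordinates)."""

    chrom: str
    start: int
    end: int
    state: str
    tumour_purity: float = 0.8

    def __post_init__(self) -> None:
        if self.state not in STATE_COPY_NUMBER:
            raise ValueError(f"unknown state {self.state!r}")
        if self.start > self.end or self.start < 1:
            raise ValueError("require 1 <= start <= end")
        if not 0.0 <= self.tumour_purity <= 1.0:
            raise ValueError("tumour_purity must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def validate_truth_segments(segments: Sequence[CnvTruthSegment]) -> None:
    """Reject overlapping truth segments within a chromosome."""
    by_chrom: dict[str, list[CnvTruthSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping truth segments on {chrom}: "
                                 f"{a.start}-{a.end} and {b.start}-{b.end}")


def expected_tumour_alt_fraction(state: str, purity: float, alt_on_affected: bool) -> float:
    """Expected tumour alt-read fraction under the allele-dosage model.

    The tumour sample is a mixture of purity ``p`` aberrant cells and
    ``1 - p`` diploid heterozygous cells.  ``alt_on_affected`` says whether
    the alternate allele sits on the haplotype that is duplicated (cn_loh,
    gain) or retained (loss).
    """
    p = purity
    cn = STATE_COPY_NUMBER[state]
    total = 2 * (1 - p) + cn * p
    if state == "neutral_het":
        alt = 1.0
    elif state == "cn_loh":
        alt = (1 - p) + (2 * p if alt_on_affected else 0.0)
    elif state == "loss":
        alt = (1 - p) + (p if alt_on_affected else 0.0)
    else:  # gain
        alt = (1 - p) + (2 * p if alt_on_affected else p)
    return alt / total


def gen_tumour_normal_sites(
    truth_segments: Sequence[CnvTruthSegment],
    site_density: float = 12.0,
    mean_depth: float = 100.0,
    seed: int = 0,
    low_gq_fraction: float = 0.02,
) -> pd.DataFrame:
    """Sample heterozygous-in-normal SNP sites along the truth segments.

    ``site_density`` is sites per Mb; tumour depths follow the segment's copy
    ratio, and tumour alt depths are binomial with the dosage-model success
    probability.  Returns a site table (one row per site, sorted by chrom and
    position) carrying VCF-style fields plus the truth state.
    """
    if mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    validate_truth_segments(truth_segments)
    rng = np.random.default_rng(seed)
    rows = []
    for seg in sorted(truth_segments, key=lambda s: (s.chrom, s.start)):
        n_sites = max(1, round(seg.length / 1e6 * site_density))
        if n_sites > seg.length:
            raise ValueError("site_density implies more sites than bases")
        # distinct positions without materialising the whole range
        pos = np.unique(rng.integers(seg.start, seg.end + 1, size=2 * n_sites + 8))
        while len(pos) < n_sites:
            extra = rng.integers(seg.start, seg.end + 1, size=2 * n_sites)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=n_sites, replace=False))
        p = seg.tumour_purity
        copy_ratio = (2 * (1 - p) + STATE_COPY_NUMBER[seg.state] * p) / 2.0

        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4

        normal_depth = rng.poisson(mean_depth, size=n_sites).clip(min=1)
        normal_alt = rng.binomial(normal_depth, 0.5)
        tumour_depth = rng.poisson(mean_depth * copy_ratio, size=n_sites).clip(min=1)
        alt_on_affected = rng.random(n_sites) < 0.5
        af = np.array([
            expected_tumour_alt_fraction(seg.state, p, bool(a)) for a in alt_on_affected
        ])
        tumour_alt = rng.binomial(tumour_depth, af)

        gq = np.full(n_sites, 99, dtype=int)
        low = rng.random(n_sites) < low_gq_fraction
        gq[low] = rng.integers(0, 14, size=int(low.sum()))

        for i in range(n_sites):
            rows.append({
                "chrom": seg.chrom,
                "pos": int(pos[i]),
                "ref": _BASES[ref_idx[i]].decode(),
                "alt": _BASES[alt_idx[i]].decode(),
                "normal_genotype": "0/1",
                "normal_ref_depth": int(normal_depth[i] - normal_alt[i]),
                "normal_alt_depth": int(normal_alt[i]),
                "tumour_ref_depth": int(tumour_depth[i] - tumour_alt[i]),
                "tumour_alt_depth": int(tumour_alt[i]),
                "genotype_quality": int(gq[i]),
                "true_state": seg.state,
                "true_alt_fraction": float(af[i]),
            })
    df = pd.DataFrame(rows)
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class EpialleleTruth:
    """Parameters of the two-epiallele bisulfite read mixture."""

    dense_fraction: float
    p_meth_dense: float = 0.99
    p_meth_background: float = 0.02
    conversion_rate: float = 0.995
    seq_error: float = 0.001
    n_reads: int = 1043
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dense_fraction", "p_meth_dense", "p_meth_background",
                     "conversion_rate", "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_meth_dense <= self.p_meth_background:
            raise ValueError("p_meth_dense must exceed p_meth_background")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


def make_amplicon(
    name: str = "synthetic_cgi_amplicon",
    length: int = 253,
    n_cpg: int = 23,
    gc_content: float = 0.7,
    seed: int = 20180618,
) -> AmpliconRef:
    """Build a synthetic GC-rich CpG-island amplicon with ``n_cpg`` CpG sites.

    A stand-in for a real promoter CpG-island amplicon: CpG dinucleotides are
    placed on an even grid and the remaining positions filled GC-rich while
    avoiding the creation of extra CpGs.
    """
    if length < 2 * n_cpg + 2:
        raise ValueError("amplicon too short for requested CpG count")
    rng = np.random.default_rng(seed)
    seq = [""] * length
    spacing = length // (n_cpg + 1)
    cpg_pos = [spacing * (i + 1) for i in range(n_cpg)]
    for p in cpg_pos:
        seq[p], seq[p + 1] = "C", "G"
    p_bases = np.array([0.2, (1 - gc_content) / 1.2, gc_content - 0.2, (1 - gc_content) / 6])
    p_bases = p_bases / p_bases.sum()
    for i in range(length):
        if seq[i]:
            continue
        while True:
            b = str(rng.choice(["C", "G", "A", "T"], p=p_bases))
            if b == "G" and i > 0 and seq[i - 1] == "C":
                continue  # would create an unannotated CpG
            if b == "C" and i + 1 < length and seq[i + 1] == "G":
                continue
            seq[i] = b
            break
    return AmpliconRef(name=name, sequence="".join(seq), cpg_positions=tuple(cpg_pos))


def gen_bisulfite_reads(
    ref: AmpliconRef, truth: EpialleleTruth
) -> tuple[list[str], pd.DataFrame]:
    """Draw full-amplicon bisulfite reads from the two-epiallele mixture.

    Each read comes from the densely methylated epiallele with probability
    ``dense_fraction`` and from either DNA strand with probability 1/2
    (bottom-strand reads are reported in top-strand orientation as G→A
    conversion patterns).  Methylated CpG cytosines are retained; unmethylated
    cytosines convert with probability ``conversion_rate`` (incomplete
    conversion leaves them unconverted); sequencing errors substitute a
    uniformly chosen different base.  Returns the reads plus a per-read truth
    table (class and strand).
    """
    if not ref.cpg_positions:
        raise ValueError("amplicon reference contains no CpG site")
    rng = np.random.default_rng(truth.seed)
    n, L = truth.n_reads, len(ref)
    seq = np.frombuffer(ref.sequence.encode(), dtype="S1")
    cpg = np.asarray(ref.cpg_positions, dtype=int)
    cpg_g = cpg + 1

    dense = rng.random(n) < truth.dense_fraction
    top = rng.random(n) < 0.5
    p_meth = np.where(dense, truth.p_meth_dense, truth.p_meth_background)
    methylated = rng.random((n, len(cpg))) < p_meth[:, None]
    converts = rng.random((n, L)) < truth.conversion_rate

    reads = np.tile(seq, (n, 1))
    is_c = seq == b"C"
    is_g = seq == b"G"
    noncpg_c = is_c.copy(); noncpg_c[cpg] = False
    noncpg_g = is_g.copy(); noncpg_g[cpg_g] = False

    # top-strand chemistry: C -> T unless protected by methylation
    conv_top = converts & noncpg_c[None, :]
    conv_top[:, cpg] = converts[:, cpg] & ~methylated
    # bottom-strand chemistry in top orientation: G -> A
    conv_bot = converts & noncpg_g[None, :]
    conv_bot[:, cpg_g] = converts[:, cpg_g] & ~methylated

    top_rows = np.where(top)[0]
    bot_rows = np.where(~top)[0]
    sub = reads[top_rows]; sub[conv_top[top_rows]] = b"T"; reads[top_rows] = sub
    sub = reads[bot_rows]; sub[conv_bot[bot_rows]] = b"A"; reads[bot_rows] = sub

    # uniform substitution errors
    err = rng.random((n, L)) < truth.seq_error
    if err.any():
        shift = rng.integers(1, 4, size=int(err.sum()))
        idx = np.searchsorted(_BASES, reads[err])  # ACGT sorted
        reads[err] = _BASES[(idx + shift) % 4]

    read_strs = [row.tobytes().decode() for row in reads]
    truth_table = pd.DataFrame({
        "read_id": [f"read_{i}" for i in range(n)],
        "true_class": np.where(dense, "dense", "background"),
        "strand": np.where(top, "top", "bottom"),
    })
    return read_strs, truth_table


@dataclass(frozen=True)
class ExpressionTruth:
    """Design of a synthetic log-scale expression matrix.

    ``effects`` maps a marker-set (stage) name to ``(group_label, effect_z)``:
    probes in that set are shifted by ``effect_z`` noise SDs in the named
    subgroup.
    """

    group_labels: tuple[str, ...]
    effects: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.5
    baseline: float = 7.0
    n_probes: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for stage, (group, eff) in self.effects.items():
            if group not in self.group_labels:
                raise ValueError(f"effect group {group!r} absent from group_labels")
            if not np.isfinite(eff):
                raise ValueError(f"effect for {stage!r} not finite")

    @property
    def n_samples(self) -> int:
        return len(self.group_labels)


def gen_expression_matrix(
    truth: ExpressionTruth,
    marker_sets: Sequence[MarkerGeneSet] = (),
    allow_overlap: bool = False,
) -> ExpressionMatrix:
    """Simulate a probes × samples log-scale matrix with marker-set shifts.

    Background values are i.i.d. normal around the baseline; each marker set
    named in ``truth.effects`` is shifted by its effect (in noise-SD units) in
    the designated subgroup.  Marker ids must exist in the probe universe
    ``P0000 .. P{n-1}``; sets must be disjoint unless ``allow_overlap``.
    """
    rng = np.random.default_rng(truth.seed)
    probe_ids = [f"P{i:05d}" for i in range(truth.n_probes)]
    universe = set(probe_ids)
    seen: set[str] = set()
    for ms in marker_sets:
        missing = [g for g in ms.gene_ids if g not in universe]
        if missing:
            raise ValueError(f"marker genes absent from probe universe: {missing[:5]}")
        if not allow_overlap and seen & set(ms.gene_ids):
            raise ValueError(f"marker set {ms.stage_name!r} overlaps a previous set")
        seen |= set(ms.gene_ids)

    values = truth.baseline + truth.noise_sd * rng.standard_normal(
        (truth.n_probes, truth.n_samples))
    probe_index = {p: i for i, p in enumerate(probe_ids)}
    groups = np.asarray(truth.group_labels)
    by_stage = {ms.stage_name: ms for ms in marker_sets}
    for stage, (group, eff) in truth.effects.items():
        if stage not in by_stage:
            raise ValueError(f"effect refers to unknown marker set {stage!r}")
        rows = [probe_index[g] for g in by_stage[stage].gene_ids]
        cols = np.where(groups == group)[0]
        values[np.ix_(rows, cols)] += eff * truth.noise_sd

    sample_ids = [f"S{j:03d}_{g}" for j, g in enumerate(truth.group_labels)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        sample_groups=pd.Series(list(truth.group_labels), index=sample_ids),
    )
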