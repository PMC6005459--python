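"""B-allele-fraction LOH/copy-number analysis of tumour/normal pairs.

From heterozygous-in-normal SNP sites this module computes mirrored B-allele
fractions and depth log-ratios, decodes per-site hidden states
{neutral, cn_loh, loss, gain} with a sticky 4-state Gaussian-emission HMM
(Viterbi), merges sites into segments, reports contiguous LOH runs with their
flanking heterozygous boundaries, and computes the fractional copy-number
aberration score: the total length of gain/loss segments divided by the total
segmented length.  Copy-neutral LOH contributes to the denominator only — it
is not a copy-number aberration.

Coordinates are 1-based and closed throughout; a segment spans its first to
last supporting site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

logger = logging.getLogger(__name__)

STATES = ("neutral", "cn_loh", "loss", "gain")
ABERRANT_COPY_STATES = frozenset({"loss", "gain"})
LOH_STATES = frozenset({"cn_loh", "loss"})

_HET_GENOTYPES = {"0/1", "1/0", "0|1", "1|0"}


@dataclass(frozen=True)
class SnpSite:
    """One biallelic tumour/normal site — the atom of BAF/LOH analysis."""

    chrom: str
    pos: int
    normal_genotype: str
    normal_depth: int
    tumour_ref_depth: int
    tumour_alt_depth: int
    genotype_quality: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if min(self.normal_depth, self.tumour_ref_depth, self.tumour_alt_depth) < 0:
            raise ValueError("depths must be non-negative")

    @property
    def tumour_depth(self) -> int:
        return self.tumour_ref_depth + self.tumour_alt_depth

    @property
    def is_heterozygous_normal(self) -> bool:
        return self.normal_genotype in _HET_GENOTYPES


@dataclass(frozen=True)
class Segment:
    """A maximal run of same-state sites (1-based closed, site-supported)."""

    chrom: str
    start: int
    end: int
    state: str
    n_sites: int
    mean_mirrored_baf: float
    mean_logratio: float

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.start > self.end or self.n_sites < 1:
            raise ValueError("invalid segment extent")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class LohRun:
    """A maximal run of contiguous filtered sites in LOH (cn_loh/loss) state.

    ``flank_left``/``flank_right`` give the position of the nearest flanking
    heterozygous (neutral-state) site — the most distal retained
    heterozygosity bounding the run — or None at a chromosome end.
    """

    chrom: str
    first_pos: int
    last_pos: int
    n_contiguous_sites: int
    copy_neutral: bool
    flank_left: int | None
    flank_right: int | None


@dataclass
class SegmentationResult:
    """Genome partition into state segments plus derived summaries."""

    segments: list[Segment]
    fractional_cna_score: float
    loh_runs: list[LohRun]
    site_states: pd.DataFrame  # chrom, pos, state per filtered site

    def __post_init__(self) -> None:
        if not 0.0 <= self.fractional_cna_score <= 1.0:
            raise ValueError("fractional_cna_score must lie in [0, 1]")


def _check_sorted(df_like: list[tuple[str, int]]) -> None:
    for (c1, p1), (c2, p2) in zip(df_like, df_like[1:]):
        if c1 == c2 and p2 < p1:
            raise ValueError("sites must be sorted by (chrom, pos)")


def filter_heterozygous_sites(
    sites: list[SnpSite],
    gq_min: float = 14,
    depth_min: int = 11,
    depth_max: int = 1001,
) -> list[SnpSite]:
    """Keep heterozygous-in-normal sites passing quality and depth bounds.

    Retains sites with genotype quality >= ``gq_min`` and read depth within
    the inclusive [``depth_min``, ``depth_max``] range in *both* the normal
    and the tumour sample.  Input must be sorted by (chrom, pos); order is
    preserved.  An empty result is allowed.
    """
    _check_sorted([(s.chrom, s.pos) for s in sites])
    return [
        s for s in sites
        if s.is_heterozygous_normal
        and s.genotype_quality >= gq_min
        and depth_min <= s.normal_depth <= depth_max
        and depth_min <= s.tumour_depth <= depth_max
    ]


def mirror_baf(baf: float | np.ndarray) -> float | np.ndarray:
    """Fold a B-allele fraction into [0.5, 1]: max(baf, 1 - baf)."""
    return np.maximum(baf, 1.0 - baf)


def compute_baf_track(sites: list[SnpSite]) -> pd.DataFrame:
    """Compute per-site BAF, mirrored BAF and normalised depth log-ratio.

    BAF is tumour alt / (ref + alt).  The log-ratio is log2(tumour depth /
    normal depth) median-centred across the genome (library-size
    normalisation).  Sites with zero tumour depth are dropped with a warning.
    """
    rows = []
    n_dropped = 0
    for s in sites:
        td = s.tumour_depth
        if td == 0 or s.normal_depth == 0:
            n_dropped += 1
            continue
        baf = s.tumour_alt_depth / td
        rows.append({
            "chrom": s.chrom, "pos": s.pos, "baf": baf,
            "mirrored_baf": float(mirror_baf(baf)),
            "logratio": np.log2(td / s.normal_depth),
        })
    if n_dropped:
        logger.warning("compute_baf_track: dropped %d site(s) with zero depth", n_dropped)
    track = pd.DataFrame(rows, columns=["chrom", "pos", "baf", "mirrored_baf", "logratio"])
    if len(track):
        track["logratio"] -= track["logratio"].median()
    return track


@dataclass(frozen=True)
class HmmParams:
    """Emission and transition parameters of the 4-state segmentation HMM.

    Emission means are (mirrored BAF, log-ratio) per state.  The mirrored-BAF
    mean for the neutral state sits above 0.5 because folding binomial noise
    at typical exome depth inflates the expectation (~0.54 at depth 100).
    Defaults correspond to the allele-dosage algebra for single-copy events
    at a representative tumour purity of 0.8; they are deliberately fixed
    (purity is not estimated) and configurable.
    """

    mean_mbaf: tuple[float, float, float, float] = (0.54, 0.90, 0.83, 0.64)
    mean_logratio: tuple[float, float, float, float] = (0.0, 0.0, -0.74, 0.49)
    sd_mbaf: float = 0.06
    sd_logratio: float = 0.25
    self_transition: float = 0.999

    def build_model(self) -> GaussianHMM:
        n = len(STATES)
        model = GaussianHMM(n_components=n, covariance_type="diag", init_params="")
        model.startprob_ = np.full(n, 1.0 / n)
        off = (1.0 - self.self_transition) / (n - 1)
        model.transmat_ = np.full((n, n), off) + np.eye(n) * (self.self_transition - off)
        model.means_ = np.column_stack([self.mean_mbaf, self.mean_logratio])
        model.covars_ = np.column_stack([
            np.full(n, self.sd_mbaf ** 2), np.full(n, self.sd_logratio ** 2)])
        return model


def segment_states(
    track: pd.DataFrame,
    params: HmmParams | None = None,
    min_sites_per_chrom: int = 5,
) -> SegmentationResult:
    """Decode per-site states and merge them into segments, per chromosome.

    Uses Viterbi decoding of the sticky Gaussian HMM on (mirrored BAF,
    log-ratio).  Chromosomes with fewer than ``min_sites_per_chrom`` sites are
    emitted as a single neutral segment with a warning.  The result also
    carries the fractional copy-number aberration score and LOH runs.
    """
    if track.empty:
        raise ValueError("empty BAF track")
    params = params or HmmParams()
    model = params.build_model()
    segments: list[Segment] = []
    state_frames = []
    for chrom, sub in track.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        X = sub[["mirrored_baf", "logratio"]].to_numpy()
        if len(sub) < min_sites_per_chrom:
            logger.warning("segment_states: %s has %d < %d sites; emitting one "
                           "neutral segment", chrom, len(sub), min_sites_per_chrom)
            states = np.zeros(len(sub), dtype=int)
        else:
            _, states = model.decode(X, algorithm="viterbi")
        state_names = np.asarray(STATES)[states]
        state_frames.append(pd.DataFrame({
            "chrom": chrom, "pos": sub["pos"].to_numpy(), "state": state_names,
        }))
        # merge consecutive same-state sites
        change = np.flatnonzero(np.diff(states)) + 1
        bounds = np.concatenate([[0], change, [len(states)]])
        for i, j in zip(bounds[:-1], bounds[1:]):
            segments.append(Segment(
                chrom=str(chrom),
                start=int(sub["pos"].iloc[i]),
                end=int(sub["pos"].iloc[j - 1]),
                state=str(state_names[i]),
                n_sites=int(j - i),
                mean_mirrored_baf=float(sub["mirrored_baf"].iloc[i:j].mean()),
                mean_logratio=float(sub["logratio"].iloc[i:j].mean()),
            ))
    site_states = pd.concat(state_frames, ignore_index=True)
    score = fractional_cna_score(segments)
    runs = find_loh_runs(site_states)
    return SegmentationResult(
        segments=segments,
        fractional_cna_score=score,
        loh_runs=runs,
        site_states=site_states,
    )


def fractional_cna_score(segments: list[Segment]) -> float:
    """Fraction of the segmented genome length in copy gain or loss.

    Sum of gain/loss segment lengths over the total length of all reported
    segments.  Copy-neutral LOH counts only in the denominator: it is loss of
    heterozygosity without copy-number change.
    """
    if not segments:
        raise ValueError("empty segment list")
    total = sum(s.length for s in segments)
    aberrant = sum(s.length for s in segments if s.state in ABERRANT_COPY_STATES)
    return aberrant / total


def find_loh_runs(site_states: pd.DataFrame) -> list[LohRun]:
    """Report maximal runs of contiguous sites in LOH (cn_loh/loss) states.

    For each run the nearest flanking heterozygous (neutral-state) site on
    each side is reported — the most distal retained heterozygosity bounding
    the run.  A run is copy-neutral if every site in it is in the cn_loh
    state.
    """
    runs: list[LohRun] = []
    for chrom, sub in site_states.groupby("chrom", sort=True):
        sub = sub.sort_values("pos").reset_index(drop=True)
        in_loh = sub["state"].isin(LOH_STATES).to_numpy()
        if not in_loh.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], in_loh.view(np.int8), [0]])))
        neutral_pos = sub.loc[sub["state"] == "neutral", "pos"].to_numpy()
        for i, j in zip(edges[0::2], edges[1::2]):  # j is one past the run end
            first, last = int(sub["pos"].iloc[i]), int(sub["pos"].iloc[j - 1])
            left = neutral_pos[neutral_pos < first]
            right = neutral_pos[neutral_pos > last]
            runs.append(LohRun(
                chrom=str(chrom),
                first_pos=first,
                last_pos=last,
                n_contiguous_sites=int(j - i),
                copy_neutral=bool((sub["state"].iloc[i:j] == "cn_loh").all()),
                flank_left=int(left.max()) if len(left) else None,
                flank_right=int(right.min()) if len(right) else None,
            ))
    return runs


def segments_frame(segments: list[Segment]) -> pd.DataFrame:
    """Tabulate segments (1-based closed coordinates)."""
    return pd.DataFrame([{
        "chrom": s.chrom, "start": s.start, "end": s.end, "state": s.state,
        "n_sites": s.n_sites, "mean_mirrored_baf": s.mean_mirrored_baf,
        "mean_logratio": s.mean_logratio, "length": s.length,
    } for s in segments])
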