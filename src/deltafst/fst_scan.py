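"""Wright Fst tracks, 5-SNP sliding-window delta-Fst and candidate windows.

The scan contrasts two population pairs at every SNP.  Per SNP, Wright's
two-population fixation index is computed from the pair's allele frequencies

    Fst = var(p) / (pbar * (1 - pbar)) = (p1 - p2)^2 / (4 * pbar * qbar)

with ``pbar`` the mean frequency of the pooled minor allele and ``var`` the
population (divide-by-two) variance.  The windowed contrast

    delta = Fst[pair B] - Fst[pair A]

is averaged over sliding windows of five consecutive SNPs within each
chromosome; positive values mark loci where the breeds of pair A are alike
while the pair-B breeds have diverged.  Top windows are selected greedily with
distance-based pruning so one selection represents each linked cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class AlleleFrequencyTable:
    """Per-(marker, breed) allele_b frequency and non-missing call count.

    ``freq_b`` and ``n_called`` are DataFrames indexed by marker_id with one
    column per breed; a marker with no calls in a breed carries ``NaN``
    frequency (the undefined flag).
    """

    freq_b: pd.DataFrame
    n_called: pd.DataFrame
    chromosome: pd.Series  # per marker_id
    position_bp: pd.Series

    @property
    def marker_ids(self) -> list[str]:
        return list(self.freq_b.index)

    @property
    def breeds(self) -> list[str]:
        return list(self.freq_b.columns)


@dataclass
class FstTrack:
    """Per-SNP Wright Fst for one breed pair, in map order."""

    pair: tuple[str, str]
    marker_ids: list[str]
    chromosome: np.ndarray
    position_bp: np.ndarray
    fst: np.ndarray

    def __post_init__(self) -> None:
        self.fst = np.asarray(self.fst, dtype=float)
        if not ((self.fst >= 0) & (self.fst <= 1)).all():
            raise ValueError("Fst values outside [0, 1]")


@dataclass(frozen=True)
class WindowScore:
    """One sliding window of consecutive SNPs with its delta-Fst summary."""

    chromosome: str
    marker_ids: tuple[str, ...]
    start_bp: int
    end_bp: int
    mean_delta_fst: float
    top_marker_id: str
    top_marker_delta_fst: float


def breed_allele_frequencies(
    panel: GenotypePanel, breeds: list[str] | None = None
) -> AlleleFrequencyTable:
    """Observed allele_b frequency per marker within each breed.

    ``freq_b = (2 * hom_b + het) / (2 * n_called)``; breeds with no calls at a
    marker get ``NaN`` (flagged undefined, never raised).
    """
    if breeds is None:
        breeds = sorted(set(panel.breeds))
    freq = {}
    ncal = {}
    for breed in breeds:
        calls = panel.calls[panel.breed_mask(breed), :]
        called = calls != MISSING
        n = called.sum(axis=0)
        dos = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            freq[breed] = np.where(n > 0, dos / (2.0 * n), np.nan)
        ncal[breed] = n
    idx = pd.Index(panel.marker_ids, name="marker_id")
    return AlleleFrequencyTable(
        freq_b=pd.DataFrame(freq, index=idx),
        n_called=pd.DataFrame(ncal, index=idx),
        chromosome=pd.Series([m.chromosome for m in panel.markers], index=idx),
        position_bp=pd.Series([m.position_bp for m in panel.markers], index=idx),
    )


def wright_fst(p1, p2):
    """Wright's two-population Fst, ``(p1 - p2)^2 / (4 * pbar * qbar)``.

    ``pbar`` is the mean of the pooled minor allele's two frequencies; the
    expression is invariant to which allele is taken, so the minor-allele
    orientation is applied for interpretability without changing the value.
    Monomorphic input (``pbar * qbar == 0``) yields 0.  Accepts scalars or
    arrays.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    # orient to the pooled minor allele
    flip = (p1 + p2) / 2.0 > 0.5
    p1 = np.where(flip, 1.0 - p1, p1)
    p2 = np.where(flip, 1.0 - p2, p2)
    pbar = (p1 + p2) / 2.0
    denom = 4.0 * pbar * (1.0 - pbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(denom > 0, (p1 - p2) ** 2 / denom, 0.0)
    return fst if fst.ndim else float(fst)


def pairwise_fst(
    freqs: AlleleFrequencyTable, pair: tuple[str, str]
) -> FstTrack:
    """Per-SNP Wright Fst track for one breed pair.

    Markers with an undefined frequency in either breed are skipped (and
    logged); markers monomorphic across the pair carry Fst 0 so downstream
    windows stay dense.
    """
    b1, b2 = pair
    for b in pair:
        if b not in freqs.freq_b.columns:
            raise KeyError(f"breed {b!r} not in frequency table")
    p1 = freqs.freq_b[b1].to_numpy()
    p2 = freqs.freq_b[b2].to_numpy()
    defined = ~np.isnan(p1) & ~np.isnan(p2)
    n_skipped = int((~defined).sum())
    if n_skipped:
        logger.info("pairwise_fst %s: skipped %d markers with undefined "
                    "frequencies", pair, n_skipped)
    fst = wright_fst(p1[defined], p2[defined])
    idx = np.flatnonzero(defined)
    all_ids = freqs.marker_ids
    return FstTrack(
        pair=pair,
        marker_ids=[all_ids[i] for i in idx],
        chromosome=freqs.chromosome.to_numpy()[idx],
        position_bp=freqs.position_bp.to_numpy()[idx].astype(int),
        fst=np.clip(fst, 0.0, 1.0),
    )


def window_delta_fst(
    track_b: FstTrack,
    track_a: FstTrack,
    window_size: int = 5,
    step: int = 1,
) -> list[WindowScore]:
    """Sliding-window mean of per-SNP ``fst_b - fst_a`` within chromosomes.

    Both tracks must cover the same markers in the same order.  Windows hold
    exactly ``window_size`` consecutive markers, never span a chromosome
    boundary, and advance by ``step`` markers.  Each window records the member
    SNP with the largest single-SNP delta (first on ties).
    """
    if track_a.marker_ids != track_b.marker_ids:
        raise ValueError("tracks cover different marker lists")
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be positive")
    delta = track_b.fst - track_a.fst
    windows: list[WindowScore] = []
    chroms = track_b.chromosome
    # contiguous runs of one chromosome, in track order
    boundaries = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(chroms)]])
    for lo, hi in zip(starts, ends):
        if hi - lo < window_size:
            logger.info("chromosome %s has %d < %d markers: no windows",
                        chroms[lo], hi - lo, window_size)
            continue
        for w0 in range(lo, hi - window_size + 1, step):
            w1 = w0 + window_size
            d = delta[w0:w1]
            top = w0 + int(np.argmax(d))
            windows.append(
                WindowScore(
                    chromosome=str(chroms[w0]),
                    marker_ids=tuple(track_b.marker_ids[w0:w1]),
                    start_bp=int(track_b.position_bp[w0]),
                    end_bp=int(track_b.position_bp[w1 - 1]),
                    mean_delta_fst=float(d.mean()),
                    top_marker_id=track_b.marker_ids[top],
                    top_marker_delta_fst=float(delta[top]),
                )
            )
    return windows


def select_top_windows(
    windows: list[WindowScore],
    n_top: int = 5,
    prune_distance_bp: int = 1_000_000,
) -> list[WindowScore]:
    """Greedy top-window selection with distance-based pruning.

    Candidates are taken in descending ``mean_delta_fst`` (ties broken by
    chromosome then start position); a candidate is skipped if it overlaps, or
    lies within ``prune_distance_bp`` of, a window already selected on the
    same chromosome — one selection per linked cluster.
    """
    if not windows:
        raise ValueError("no windows to select from")
    order = sorted(
        windows,
        key=lambda w: (-w.mean_delta_fst, _chrom_key(w.chromosome), w.start_bp),
    )
    selected: list[WindowScore] = []
    for cand in order:
        if len(selected) >= n_top:
            break
        clash = any(
            s.chromosome == cand.chromosome
            and cand.start_bp <= s.end_bp + prune_distance_bp
            and cand.end_bp >= s.start_bp - prune_distance_bp
            for s in selected
        )
        if not clash:
            selected.append(cand)
    return selected


def _chrom_key(chrom: str) -> tuple[int, int | str]:
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def windows_to_frame(windows: list[WindowScore]) -> pd.DataFrame:
    """Tabular view of a window list, for TSV export."""
    return pd.DataFrame(
        {
            "chromosome": [w.chromosome for w in windows],
            "start_bp": [w.start_bp for w in windows],
            "end_bp": [w.end_bp for w in windows],
            "mean_delta_fst": [w.mean_delta_fst for w in windows],
            "top_marker_id": [w.top_marker_id for w in windows],
            "top_marker_delta_fst": [w.top_marker_delta_fst for w in windows],
            "marker_ids": [",".join(w.marker_ids) for w in windows],
        }
    )
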