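"""Marker quality control and sample-relatedness checks.

Marker QC mirrors the filters applied before a breed-pair divergence scan:
call rate, minor allele frequency, presence of calls in both breeds of the
analysed pair, and removal of X-chromosome markers.  Filters are applied in
that order and each marker is attributed to the first filter that removes it,
so the removal counts and the remaining count always sum to the input count.

Relatedness is the PLINK ``--genome`` style method-of-moments PI_HAT:
``P(IBD=2) + 0.5 * P(IBD=1)`` estimated from identity-by-state counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel

logger = logging.getLogger(__name__)

X_CHROMOSOMES = {"X", "x"}  # horse chr23 is autosomal (DMRT3), never X


@dataclass(frozen=True)
class QcReport:
    """Tally of markers removed by each filter, in application order."""

    n_removed_call_rate: int
    n_removed_maf: int
    n_removed_not_common: int
    n_removed_x: int
    n_remaining: int
    thresholds: tuple[float, float]  # (min_call_rate, min_maf)

    @property
    def n_input(self) -> int:
        return (
            self.n_removed_call_rate
            + self.n_removed_maf
            + self.n_removed_not_common
            + self.n_removed_x
            + self.n_remaining
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filter": ["call_rate", "maf", "not_common", "x_chromosome",
                           "remaining"],
                "n_markers": [
                    self.n_removed_call_rate,
                    self.n_removed_maf,
                    self.n_removed_not_common,
                    self.n_removed_x,
                    self.n_remaining,
                ],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def apply_marker_qc(
    panel: GenotypePanel,
    breed_pair: tuple[str, str],
    min_call_rate: float = 0.99,
    min_maf: float = 0.00001,
    drop_x: bool = True,
) -> tuple[GenotypePanel, QcReport]:
    """Filter markers for a breed-pair analysis and report removals.

    Removes, in order: markers whose call rate over the two breeds' samples is
    below ``min_call_rate``; markers whose pooled minor allele frequency over
    the pair is below ``min_maf`` (at the default threshold this strips only
    monomorphic markers); markers with zero non-missing calls in either breed
    of the pair; markers on the X chromosome (unless ``drop_x`` is false).
    All samples are retained; only markers are filtered.
    """
    for breed in breed_pair:
        panel.breed_mask(breed)  # raises KeyError if absent

    mask_pair = panel.breed_mask(breed_pair[0]) | panel.breed_mask(breed_pair[1])
    calls = panel.calls[mask_pair, :]
    called = calls != MISSING
    n_pair = calls.shape[0]

    call_rate = called.sum(axis=0) / n_pair
    dosage_sum = np.where(called, calls, 0).sum(axis=0)
    n_called = called.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq_b = np.where(n_called > 0, dosage_sum / (2.0 * n_called), np.nan)
    maf = np.fmin(freq_b, 1.0 - freq_b)

    mask_a = panel.breed_mask(breed_pair[0])
    mask_b = panel.breed_mask(breed_pair[1])
    called_a = (panel.calls[mask_a, :] != MISSING).sum(axis=0)
    called_b = (panel.calls[mask_b, :] != MISSING).sum(axis=0)

    is_x = np.array(
        [m.chromosome in X_CHROMOSOMES for m in panel.markers], dtype=bool
    )

    removed = np.zeros(panel.n_markers, dtype=int)  # 0 = keep, else filter idx
    fail_call = call_rate < min_call_rate
    removed[fail_call & (removed == 0)] = 1
    fail_maf = np.isnan(maf) | (maf < min_maf)
    removed[fail_maf & (removed == 0)] = 2
    fail_common = (called_a == 0) | (called_b == 0)
    removed[fail_common & (removed == 0)] = 3
    if drop_x:
        removed[is_x & (removed == 0)] = 4

    keep = np.flatnonzero(removed == 0)
    report = QcReport(
        n_removed_call_rate=int((removed == 1).sum()),
        n_removed_maf=int((removed == 2).sum()),
        n_removed_not_common=int((removed == 3).sum()),
        n_removed_x=int((removed == 4).sum()),
        n_remaining=len(keep),
        thresholds=(min_call_rate, min_maf),
    )
    return panel.subset_markers(keep), report


# -- identity by descent -----------------------------------------------------


def pairwise_ibd(panel: GenotypePanel) -> pd.DataFrame:
    """Method-of-moments genome-wide relatedness for every unordered pair.

    Follows the PLINK ``--genome`` construction: per pair, count IBS 0/1/2
    states over jointly called autosomal markers, equate them to their
    expectations under IBD 0/1/2 given panel allele frequencies, and solve for
    the IBD-state proportions.  Returns a frame with columns ``sample_1``,
    ``sample_2``, ``p_ibd0``, ``p_ibd1``, ``p_ibd2``, ``pi_hat``; proportions
    are clamped to [0, 1] and renormalised, ``pi_hat = p_ibd2 + p_ibd1 / 2``.

    Allele frequencies are estimated from the panel itself.  Fewer than 100
    markers triggers a warning (unstable estimates), not an error.
    """
    if panel.n_samples < 2:
        raise ValueError("pairwise_ibd needs at least two samples")
    autosomal = [j for j, m in enumerate(panel.markers)
                 if m.chromosome not in X_CHROMOSOMES]
    if len(autosomal) < 100:
        logger.warning(
            "pairwise_ibd: only %d autosomal markers; estimates are unstable",
            len(autosomal),
        )
    calls = panel.calls[:, autosomal].astype(float)
    calls[calls == MISSING] = np.nan

    # panel-wide allele counts per marker: x copies of allele_b, y of allele_a
    x = np.nansum(calls, axis=0)
    tot = 2.0 * np.sum(~np.isnan(calls), axis=0)
    y = tot - x
    # markers fixed in the panel, or with fewer than 4 observed alleles, are
    # uninformative for the IBS-based moments
    poly = (x > 0) & (y > 0) & (tot >= 4)
    calls = calls[:, poly]
    x, y, tot = x[poly], y[poly], tot[poly]

    # expected IBS-state probabilities per marker given IBD state, with the
    # falling-factorial small-sample corrections (frequencies are estimated
    # from this very panel, so plug-in powers of p would bias pi_hat upward)
    d4 = tot * (tot - 1) * (tot - 2) * (tot - 3)
    d3 = tot * (tot - 1) * (tot - 2)
    e0_ibd0 = 2.0 * x * (x - 1) * y * (y - 1) / d4
    e1_ibd0 = (4.0 * x * (x - 1) * (x - 2) * y
               + 4.0 * x * y * (y - 1) * (y - 2)) / d4
    e2_ibd0 = 1.0 - e0_ibd0 - e1_ibd0
    e1_ibd1 = (2.0 * x * (x - 1) * y + 2.0 * x * y * (y - 1)) / d3
    e2_ibd1 = 1.0 - e1_ibd1

    rows = []
    n = panel.n_samples
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = calls[i], calls[j]
            ok = ~np.isnan(gi) & ~np.isnan(gj)
            if ok.sum() == 0:
                rows.append((panel.sample_ids[i], panel.sample_ids[j],
                             np.nan, np.nan, np.nan, np.nan))
                continue
            diff = np.abs(gi[ok] - gj[ok])
            n_ibs0 = float((diff == 2).sum())
            n_ibs1 = float((diff == 1).sum())
            n_ibs2 = float((diff == 0).sum())
            m = float(ok.sum())

            s0_0 = e0_ibd0[ok].sum()
            s1_0 = e1_ibd0[ok].sum()
            s2_0 = e2_ibd0[ok].sum()
            s1_1 = e1_ibd1[ok].sum()
            s2_1 = e2_ibd1[ok].sum()

            p0 = n_ibs0 / s0_0 if s0_0 > 0 else 0.0
            p1 = (n_ibs1 - p0 * s1_0) / s1_1 if s1_1 > 0 else 0.0
            p2 = (n_ibs2 - p0 * s2_0 - p1 * s2_1) / m

            # pi_hat is formed from the raw moment estimates and clamped only
            # at the end; clamping each proportion first would bias pairs
            # near the boundaries (true pi_hat 0 would average positive)
            pi_hat = float(np.clip(p2 + 0.5 * p1, 0.0, 1.0))
            props = np.clip([p0, p1, p2], 0.0, 1.0)
            total = props.sum()
            if total > 0:
                props = props / total
            rows.append((panel.sample_ids[i], panel.sample_ids[j],
                         props[0], props[1], props[2], pi_hat))

    return pd.DataFrame(
        rows,
        columns=["sample_1", "sample_2", "p_ibd0", "p_ibd1", "p_ibd2", "pi_hat"],
    )


def flag_related_pairs(
    ibd: pd.DataFrame, max_pi_hat: float = 0.25
) -> pd.DataFrame:
    """Subset of the IBD table with ``pi_hat`` above the relatedness ceiling."""
    return ibd[ibd["pi_hat"] > max_pi_hat].reset_index(drop=True)
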