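"""EM haplotype-frequency estimation, expected dosages and haplotype regression.

Unphased multilocus genotypes over an ordered SNP window are resolved by the
classical expectation–maximisation algorithm: the E-step distributes each
individual's probability mass over the haplotype pairs compatible with its
genotype, proportional to ``2 f_i f_j`` (``f_i^2`` for homozygous pairs); the
M-step re-estimates pool frequencies from the expected pair counts.  The
log-likelihood is non-decreasing by construction and is recorded per
iteration.

Downstream, expected per-individual haplotype dosages (summing to 2) enter an
ordinary least-squares regression of a transformed performance trait on all
common haplotypes except the most frequent one, which serves as the base;
haplotypes rarer than the configurable threshold (default 2%) are excluded
from the design.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .genotype_io import MISSING, GenotypePanel

logger = logging.getLogger(__name__)

MAX_WINDOW_SNPS = 12  # full-enumeration bound: 2^12 haplotypes


@dataclass
class HaplotypeSet:
    """EM-estimated haplotype pool over an ordered SNP window.

    ``haplotypes[h]`` is an allele string of length k (actual allele
    characters, e.g. ``"TGTAAAG"``); ``frequencies[h]`` its pool frequency.
    ``pair_posteriors[i]`` lists ``(h1, h2, prob)`` over the genotype-
    compatible haplotype pairs of included individual ``i`` (probabilities sum
    to 1).  Individuals with any missing call in the window are excluded and
    listed separately.
    """

    snp_ids: list[str]
    haplotypes: list[str]
    frequencies: np.ndarray
    sample_ids: list[str]
    pair_posteriors: list[list[tuple[int, int, float]]]
    excluded_sample_ids: list[str]
    rare_threshold: float = 0.02
    n_iter: int = 0
    converged: bool = True
    log_likelihood: list[float] = field(default_factory=list)

    @property
    def is_rare(self) -> np.ndarray:
        return self.frequencies < self.rare_threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype": self.haplotypes,
                "frequency": self.frequencies,
                "rare": self.is_rare,
            }
        ).sort_values("frequency", ascending=False, ignore_index=True)


def _compatible_pairs(genotype: np.ndarray) -> list[tuple[tuple, tuple]]:
    """All unordered haplotype pairs consistent with a 0/1/2 genotype vector.

    Haplotypes are 0/1 tuples (1 = allele_b).  Heterozygous sites double the
    resolutions; ``2^(h-1)`` pairs for h het sites (one pair when h = 0).
    """
    het = np.flatnonzero(genotype == 1)
    base = np.where(genotype == 2, 1, 0)
    if het.size == 0:
        h = tuple(int(x) for x in base)
        return [(h, h)]
    pairs = []
    seen = set()
    for assign in itertools.product((0, 1), repeat=len(het)):
        h1 = base.copy()
        h2 = base.copy()
        h1[het] = assign
        h2[het] = 1 - np.asarray(assign)
        key = tuple(sorted((tuple(int(x) for x in h1), tuple(int(x) for x in h2))))
        if key not in seen:
            seen.add(key)
            pairs.append(key)
    return pairs


def em_frequencies(
    panel: GenotypePanel,
    snp_ids: list[str],
    tol: float = 1e-6,
    max_iter: int = 1000,
    rare_threshold: float = 0.02,
    seed: int | None = None,
) -> HaplotypeSet:
    """EM haplotype-frequency estimation over an ordered SNP window.

    Initialisation is the deterministic uniform distribution over haplotypes
    compatible with at least one individual, so results are reproducible and
    the ``seed`` only matters for optional random restarts (currently none are
    taken — the likelihood surface for the window sizes supported here is
    well-behaved in practice).  Iteration stops when the largest frequency
    change falls below ``tol``; non-convergence at ``max_iter`` logs a warning
    with the last delta rather than raising.
    """
    k = len(snp_ids)
    if k > MAX_WINDOW_SNPS:
        raise ValueError(
            f"{k} SNPs exceeds the enumeration bound of {MAX_WINDOW_SNPS}"
        )
    if k == 0:
        raise ValueError("empty SNP window")
    cols = [panel.marker_index(s) for s in snp_ids]
    geno = panel.calls[:, cols]

    complete = ~(geno == MISSING).any(axis=1)
    included = np.flatnonzero(complete)
    excluded_ids = [panel.sample_ids[i] for i in np.flatnonzero(~complete)]
    if included.size == 0:
        raise ValueError("no individual fully genotyped in the SNP window")

    pair_lists = [_compatible_pairs(geno[i]) for i in included]

    # haplotype universe: union of compatible haplotypes over individuals
    universe: dict[tuple, int] = {}
    for pairs in pair_lists:
        for h1, h2 in pairs:
            for h in (h1, h2):
                if h not in universe:
                    universe[h] = len(universe)
    hap_tuples = list(universe)
    idx_pairs = [
        [(universe[h1], universe[h2]) for h1, h2 in pairs] for pairs in pair_lists
    ]

    n_hap = len(hap_tuples)
    n_ind = included.size
    freqs = np.full(n_hap, 1.0 / n_hap)
    loglik_trace: list[float] = []
    converged = False
    last_delta = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        new = np.zeros(n_hap)
        loglik = 0.0
        posteriors: list[np.ndarray] = []
        for pairs in idx_pairs:
            w = np.array(
                [
                    (2.0 if a != b else 1.0) * freqs[a] * freqs[b]
                    for a, b in pairs
                ]
            )
            total = w.sum()
            if total <= 0:
                w = np.full(len(pairs), 1.0 / len(pairs))
                total = 1.0
                loglik += -np.inf
            else:
                w = w / total
                loglik += np.log(total)
            posteriors.append(w)
            for (a, b), wi in zip(pairs, w):
                new[a] += wi
                new[b] += wi
        new /= 2.0 * n_ind
        loglik_trace.append(loglik)
        last_delta = float(np.abs(new - freqs).max())
        freqs = new
        if last_delta < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "EM did not converge in %d iterations (last max change %.3g)",
            max_iter, last_delta,
        )

    # final posteriors at the converged frequencies
    final_posteriors: list[list[tuple[int, int, float]]] = []
    for pairs in idx_pairs:
        w = np.array(
            [(2.0 if a != b else 1.0) * freqs[a] * freqs[b] for a, b in pairs]
        )
        total = w.sum()
        w = w / total if total > 0 else np.full(len(pairs), 1.0 / len(pairs))
        final_posteriors.append(
            [(a, b, float(wi)) for (a, b), wi in zip(pairs, w)]
        )

    # render haplotypes as allele characters in SNP order
    alleles = [
        (panel.markers[c].allele_a, panel.markers[c].allele_b) for c in cols
    ]
    hap_strings = [
        "".join(alleles[s][bit] for s, bit in enumerate(h)) for h in hap_tuples
    ]

    return HaplotypeSet(
        snp_ids=list(snp_ids),
        haplotypes=hap_strings,
        frequencies=freqs,
        sample_ids=[panel.sample_ids[i] for i in included],
        pair_posteriors=final_posteriors,
        excluded_sample_ids=excluded_ids,
        rare_threshold=rare_threshold,
        n_iter=it,
        converged=converged,
        log_likelihood=loglik_trace,
    )


def haplotype_dosages(hs: HaplotypeSet) -> pd.DataFrame:
    """Expected per-individual count of each haplotype (rows sum to 2).

    ``dosage(h) = sum over compatible pairs of posterior * (copies of h)``.
    Indexed by the included sample ids, one column per haplotype string.
    """
    n = len(hs.sample_ids)
    dos = np.zeros((n, len(hs.haplotypes)))
    for i, pairs in enumerate(hs.pair_posteriors):
        for a, b, w in pairs:
            dos[i, a] += w
            dos[i, b] += w
    return pd.DataFrame(dos, index=pd.Index(hs.sample_ids, name="sample_id"),
                        columns=hs.haplotypes)


def haplotype_glm(
    trait: pd.Series,
    hs: HaplotypeSet,
    covariates: pd.DataFrame,
    categorical: tuple[str, ...] = ("sex", "country", "dmrt3"),
) -> pd.DataFrame:
    """Regress a transformed trait on common-haplotype dosages plus covariates.

    The most frequent haplotype is the base (omitted from the design; ties
    broken lexicographically and logged); haplotypes below the rare threshold
    are excluded entirely.  Remaining dosages enter an OLS fit together with
    the covariate columns (those named in ``categorical`` as factors).  Returns
    a frame with haplotype, frequency, coefficient, p_value (base row carries
    NaNs; rare haplotypes are omitted).
    """
    common = np.flatnonzero(~hs.is_rare)
    if common.size < 2:
        raise ValueError("need at least two non-rare haplotypes")
    order = sorted(common, key=lambda h: (-hs.frequencies[h], hs.haplotypes[h]))
    base = order[0]
    ties = [h for h in common if hs.frequencies[h] == hs.frequencies[base]]
    if len(ties) > 1:
        logger.info("base-haplotype tie among %s; lexicographic winner %s",
                    [hs.haplotypes[h] for h in ties], hs.haplotypes[base])
    modeled = [h for h in order[1:]]

    dosages = haplotype_dosages(hs)
    df = covariates.copy()
    df["_trait"] = trait
    hap_cols = {}
    for h in modeled:
        col = f"hap_{h}"
        hap_cols[h] = col
        df[col] = dosages[hs.haplotypes[h]].reindex(df.index)
    df = df.dropna(subset=["_trait"] + list(hap_cols.values()))

    terms = [f"C({c})" if c in categorical else c for c in covariates.columns]
    terms += list(hap_cols.values())
    model = smf.ols("_trait ~ " + " + ".join(terms), data=df).fit()

    rows = [
        {
            "haplotype": hs.haplotypes[base],
            "frequency": float(hs.frequencies[base]),
            "coefficient": np.nan,
            "p_value": np.nan,
            "is_base": True,
        }
    ]
    for h in modeled:
        col = hap_cols[h]
        rows.append(
            {
                "haplotype": hs.haplotypes[h],
                "frequency": float(hs.frequencies[h]),
                "coefficient": float(model.params[col]),
                "p_value": float(model.pvalues[col]),
                "is_base": False,
            }
        )
    return pd.DataFrame(rows)
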