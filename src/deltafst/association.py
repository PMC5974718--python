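"""Single-SNP association of candidate markers with racing-performance traits.

Traits are transformed to approximate normality before modelling: earnings as
``ln(x + 1000)`` (Norwegian amounts converted to SEK at the long-run mean
rate 0.95 first), best race times as ``ln(x - 68.2)`` with 68.2 s/km acting
as a physiological lower bound, and count/frequency traits as
``log10(x + 1)``.  Each transformed trait is fitted by ordinary least squares
with the candidate genotype as an unordered three-level factor plus fixed
effects of sex, age, country of registration and the DMRT3 gait-locus
genotype; the number of career starts is added for career-total traits only.
The three pairwise genotype contrasts are read off the single fit.  Nominal
(uncorrected) p-values are reported.

Linkage disequilibrium between two markers is summarised by D' and r^2 from
EM-estimated two-locus haplotype frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .genotype_io import GenotypePanel
from .haplotypes import em_frequencies

logger = logging.getLogger(__name__)

#: Traits whose transform is ln(x + 1000), after NOK -> SEK conversion.
EARNINGS_TRAITS = ("earnings", "earnings_per_start")
#: Traits whose transform is ln(x - 68.2); x is seconds per km.
TIME_TRAITS = ("time_volt", "time_auto")
#: Count and frequency traits, transformed log10(x + 1).
LOG10_TRAITS = ("n_starts", "n_wins", "n_placings", "win_freq", "placing_freq")

TIME_FLOOR = 68.2
NOK_TO_SEK = 0.95

#: Traits for which the number-of-starts covariate is applicable: career
#: totals, not per-start rates or time records (and not n_starts itself).
STARTS_COVARIATE_TRAITS = ("n_wins", "n_placings", "earnings")

REQUIRED_COLUMNS = (
    "sample_id", "sex", "age", "country", "n_starts", "n_wins", "n_placings",
    "earnings", "currency", "dmrt3",
)


@dataclass(frozen=True)
class TraitTransformSpec:
    """Mapping from trait name to its normalising transform."""

    transforms: dict = field(default_factory=lambda: {
        **{t: "ln_plus_1000" for t in EARNINGS_TRAITS},
        **{t: "ln_minus_68_2" for t in TIME_TRAITS},
        **{t: "log10_plus_1" for t in LOG10_TRAITS},
    })
    nok_to_sek_rate: float = NOK_TO_SEK


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise genotype contrast for one trait, on the transformed scale."""

    trait: str
    genotype_pair: tuple[str, str]
    estimate: float
    p_value: float
    n_per_genotype: dict


def validate_phenotypes(table: pd.DataFrame) -> None:
    """Check the phenotype table's schema and internal consistency."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    if (table["n_wins"] > table["n_placings"]).any():
        raise ValueError("n_wins exceeds n_placings for some horses")
    if (table["n_placings"] > table["n_starts"]).any():
        raise ValueError("n_placings exceeds n_starts for some horses")


def transform_traits(
    table: pd.DataFrame, spec: TraitTransformSpec | None = None
) -> pd.DataFrame:
    """Apply the normalising transforms, returning a copy of the table.

    Earnings-type columns in NOK are first multiplied by the SEK exchange
    rate; transformed columns replace the raw ones (covariates pass through).
    Horses lacking a time record keep ``NaN`` there and drop out of that
    trait's model only.  A recorded time at or below the 68.2 s/km floor is a
    domain error naming the horse.
    """
    spec = spec or TraitTransformSpec()
    out = table.copy()
    is_nok = out.get("currency")
    for trait, kind in spec.transforms.items():
        if trait not in out.columns:
            continue
        x = out[trait].astype(float)
        if kind == "ln_plus_1000":
            if is_nok is not None:
                x = x.where(is_nok != "NOK", x * spec.nok_to_sek_rate)
            out[trait] = np.log(x + 1000.0)
        elif kind == "ln_minus_68_2":
            bad = x.notna() & (x <= TIME_FLOOR)
            if bad.any():
                who = table.loc[bad, "sample_id"].tolist() \
                    if "sample_id" in table.columns else list(table.index[bad])
                raise ValueError(
                    f"race time at or below {TIME_FLOOR} s/km for horses: {who}"
                )
            out[trait] = np.log(x - TIME_FLOOR)
        elif kind == "log10_plus_1":
            out[trait] = np.log10(x + 1.0)
        elif kind != "identity":
            raise ValueError(f"unknown transform {kind!r} for trait {trait!r}")
    if is_nok is not None:
        out["currency"] = "SEK"
    return out


def starts_covariate_applicable(trait: str) -> bool:
    return trait in STARTS_COVARIATE_TRAITS


def fit_single_snp_model(
    table: pd.DataFrame,
    trait: str,
    genotype_col: str = "genotype",
    covariates: tuple[str, ...] = ("sex", "age", "country", "dmrt3"),
    include_starts: bool | None = None,
) -> list[ContrastResult]:
    """OLS of a transformed trait on a 3-level genotype plus fixed effects.

    ``include_starts=None`` applies the career-total rule automatically.
    Returns the pairwise contrasts among observed genotype classes, each with
    the two-sided p-value of its linear-contrast t-test within the single fit
    (equivalent to subset refits under homoscedasticity).  Contrast estimates
    are on the transformed scale, oriented ``first minus second``.
    """
    if include_starts is None:
        include_starts = starts_covariate_applicable(trait)
    cols = [trait, genotype_col, *covariates]
    if include_starts and "n_starts" not in cols:
        cols.append("n_starts")
    df = table[cols].dropna()
    if df.empty:
        raise ValueError(f"no complete observations for trait {trait!r}")
    levels = sorted(df[genotype_col].astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"genotype {genotype_col!r} has fewer than 2 classes")
    df = df.assign(**{genotype_col: df[genotype_col].astype(str)})

    categorical = {"sex", "country", "dmrt3"}
    terms = [f"C({genotype_col})"]
    terms += [f"C({c})" if c in categorical else c for c in covariates]
    if include_starts:
        terms.append("n_starts")
    formula = f"{trait} ~ " + " + ".join(terms)
    try:
        model = smf.ols(formula, data=df).fit()
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare numeric path
        raise ValueError(
            "singular design matrix; consider merging sparse covariate "
            "categories"
        ) from exc
    if np.isnan(model.params).any() or model.df_resid <= 0:
        raise ValueError(
            "singular design matrix; consider merging sparse covariate "
            "categories"
        )

    counts = df[genotype_col].value_counts().to_dict()
    exog_names = model.model.exog_names

    def level_vector(level: str) -> np.ndarray:
        v = np.zeros(len(exog_names))
        name = f"C({genotype_col})[T.{level}]"
        if name in exog_names:
            v[exog_names.index(name)] = 1.0
        return v

    results = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            contrast = level_vector(levels[i]) - level_vector(levels[j])
            tt = model.t_test(contrast)
            results.append(
                ContrastResult(
                    trait=trait,
                    genotype_pair=(levels[i], levels[j]),
                    estimate=float(np.squeeze(tt.effect)),
                    p_value=float(np.squeeze(tt.pvalue)),
                    n_per_genotype={g: int(counts.get(g, 0)) for g in levels},
                )
            )
    return results


def association_grid(
    table: pd.DataFrame,
    traits: list[str],
    genotype_col: str = "genotype",
    covariates: tuple[str, ...] = ("sex", "age", "country", "dmrt3"),
) -> pd.DataFrame:
    """Trait x contrast grid of estimates and p-values for a report table."""
    rows = []
    for trait in traits:
        for res in fit_single_snp_model(table, trait, genotype_col, covariates):
            rows.append(
                {
                    "trait": trait,
                    "contrast": f"{res.genotype_pair[0]} vs {res.genotype_pair[1]}",
                    "estimate": res.estimate,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LdResult:
    d_prime: float
    r_squared: float
    defined: bool = True


def pairwise_ld(
    panel: GenotypePanel, marker_1: str, marker_2: str
) -> LdResult:
    """D' and r^2 between two markers from EM two-locus haplotype frequencies.

    ``D = p_AB - p_A p_B``; ``D' = |D| / D_max`` with the usual bound, and
    ``r^2 = D^2 / (p_A p_a p_B p_b)``.  A marker monomorphic in the panel
    makes both measures undefined (flagged, not raised).
    """
    hs = em_frequencies(panel, [marker_1, marker_2], tol=1e-10)
    cols = [panel.marker_index(m) for m in (marker_1, marker_2)]
    # frequency of allele_b at each locus, from the haplotype pool
    p_a = 0.0  # allele_b at locus 1
    p_b = 0.0
    p_ab = 0.0
    b1 = panel.markers[cols[0]].allele_b
    b2 = panel.markers[cols[1]].allele_b
    for hap, f in zip(hs.haplotypes, hs.frequencies):
        carries_1 = hap[0] == b1
        carries_2 = hap[1] == b2
        p_a += f * carries_1
        p_b += f * carries_2
        p_ab += f * (carries_1 and carries_2)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return LdResult(np.nan, np.nan, defined=False)
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LdResult(float(min(d_prime, 1.0)), float(min(r2, 1.0)))
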