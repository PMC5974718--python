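"""Synthetic genotype panels and race-record phenotypes for pipeline testing.

The generator emulates the statistical structure the analysis assumes:

* three breeds diverged from a common ancestral allele-frequency spectrum
  under the Balding–Nichols model (per-breed Beta-distributed frequencies
  whose drift parameter is interpretable as that breed's Fst against the
  ancestor), with genotypes drawn under within-breed Hardy–Weinberg;
* an implanted selection signature — a short span of markers where the two
  trotting breeds share high frequencies while the draught breed diverges,
  patterned on the reported frequencies of the focal region;
* a 7-SNP block in strong linkage disequilibrium, induced by sampling whole
  haplotypes from the published four-haplotype pool rather than independent
  markers;
* race-record phenotypes in which a latent performance variable carries fixed
  covariate effects plus a recessive penalty on homozygotes for the focal
  SNP's reference allele, and each recorded trait is the inverse of its
  normalising transform applied to that latent scale.

Everything is reproducible bit-for-bit from the config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .fst_scan import wright_fst
from .genotype_io import (
    GenotypePanel,
    MarkerInfo,
    write_breed_tsv,
    write_ped_map,
)

# ---------------------------------------------------------------------------
# configuration


def drift_from_fst_targets(
    targets: dict[tuple[str, str], float] | None = None,
    breeds: tuple[str, ...] = datasets.BREEDS,
) -> tuple[float, ...]:
    """Per-breed Balding–Nichols drift solving the three pairwise Fst targets.

    With ``s = F_i + F_j``, the genome-wide mean of the per-SNP Wright Fst
    between breeds i and j is well approximated by
    ``t = s * (1 - 0.42 * s) / (4 - s)`` over the broad ancestral spectrum
    used here (the first factor is the ratio-of-expectations term, the second
    an empirical second-order correction for frequency pile-up near fixation;
    accurate to ~1% relative for s up to 0.6).  Each target t is inverted for
    s via the quadratic root and the three pair equations are solved linearly
    for the per-breed parameters.
    """
    targets = targets or datasets.GENOME_FST_TARGETS
    s = {}
    for (b1, b2), t in targets.items():
        # 0.42 s^2 - (1 + t) s + 4 t = 0, smaller root
        disc = (1.0 + t) ** 2 - 4 * 0.42 * 4.0 * t
        s[frozenset((b1, b2))] = ((1.0 + t) - np.sqrt(disc)) / (2 * 0.42)
    if len(breeds) != 3:
        raise ValueError("drift calibration requires exactly three breeds")
    a, b, c = breeds
    s_ab = s[frozenset((a, b))]
    s_ac = s[frozenset((a, c))]
    s_bc = s[frozenset((b, c))]
    f_a = (s_ab + s_ac - s_bc) / 2.0
    f_b = s_ab - f_a
    f_c = s_ac - f_a
    drift = (float(f_a), float(f_b), float(f_c))
    if any(f <= 0 or f >= 1 for f in drift):
        raise ValueError(f"targets imply drift outside (0, 1): {drift}")
    return drift


@dataclass(frozen=True)
class SelectedLocusSpec:
    """A span of markers implanted with a fixed breed-frequency triplet.

    The triplet gives each breed's frequency of ``allele_b`` and follows the
    reported focal-region pattern: the first and third breeds alike, the
    second divergent.  The default covers a full scan window of five markers
    so the signature survives window averaging.
    """

    chromosome: str = "3"
    span: int = 5
    freqs: tuple[float, float, float] = (0.80, 0.15, 0.75)
    allele_a: str = "C"
    allele_b: str = "T"

    def __post_init__(self) -> None:
        f1, f2, f3 = self.freqs
        if abs(f1 - f3) > 0.1 or abs(f1 - f2) < 0.5:
            raise ValueError(
                "selected-locus triplet must have breeds 1 and 3 within 0.1 "
                "and breed 2 at least 0.5 apart from breed 1"
            )


@dataclass(frozen=True)
class LdBlockSpec:
    """A 7-SNP haplotype block sampled from a fixed haplotype pool."""

    chromosome: str = datasets.LD_BLOCK_CHROMOSOME
    positions: tuple[int, ...] = tuple(datasets.LD_BLOCK_POSITIONS)
    haplotypes: tuple[str, ...] = tuple(datasets.LD_BLOCK_HAPLOTYPES)
    frequencies: tuple[float, ...] = tuple(datasets.LD_BLOCK_FREQUENCIES)
    focal_index: int = datasets.LD_BLOCK_FOCAL_INDEX

    def __post_init__(self) -> None:
        # published pool frequencies are rounded to 2 decimals and may sum
        # slightly off 1; they are renormalised at sampling time
        if abs(sum(self.frequencies) - 1.0) > 0.05:
            raise ValueError("haplotype frequencies must sum to ~1")
        k = len(self.positions)
        if any(len(h) != k for h in self.haplotypes):
            raise ValueError("haplotype length must match position count")

    def site_alleles(self) -> list[tuple[str, str]]:
        """(allele_a, allele_b) per site; alphabetical order, a before b."""
        out = []
        for s in range(len(self.positions)):
            chars = sorted({h[s] for h in self.haplotypes})
            if len(chars) == 1:
                chars.append("0")
            elif len(chars) != 2:
                raise ValueError(f"site {s} is not biallelic: {chars}")
            out.append((chars[0], chars[1]))
        return out


@dataclass(frozen=True)
class PhenoModelSpec:
    """Latent-performance model behind the simulated race records.

    ``genotype_effect`` is the shift, in units of the latent noise standard
    deviation, applied to horses homozygous for the focal marker's
    ``allele_a`` (the recessive penalty class); covariate effects are on the
    same standardised scale.  Intercepts and scales per trait were set to
    reproduce realistic Swedish trotting-career ranges (median ~25 starts,
    median earnings near 80 kSEK, best times around 90 s/km).
    """

    genotype_effect: float = -0.5
    focal_marker_id: str | None = None  # None: block focal SNP, else locus middle
    sex_effects: tuple[float, float, float] = (-0.15, 0.0, 0.10)  # mare/geld/stall
    age_effect: float = 0.03  # per year, centred at 10
    country_effect_no: float = -0.05
    dmrt3_effects: tuple[float, float, float] = (0.30, 0.10, 0.0)  # AA/CA/CC
    dmrt3_a_freq: float = 0.6
    p_country_no: float = 0.2
    p_missing_time_volt: float = 0.10
    p_missing_time_auto: float = 0.15
    earnings_intercept: float = 11.3  # ln(SEK + 1000) scale
    earnings_scale: float = 1.4
    starts_intercept: float = 1.30  # log10(x + 1) scale
    starts_scale: float = 0.45
    time_volt_intercept: float = 3.10  # ln(s/km - 68.2) scale
    time_auto_intercept: float = 3.02
    time_scale: float = 0.13


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic dataset.

    Scan-scale defaults mirror the study's divergence analysis: 11/19/12
    horses per breed and a drift triplet calibrated to the published
    genome-wide Fst levels.  For association-scale data use
    :func:`association_config`.
    """

    seed: int = 0
    breeds: tuple[str, ...] = datasets.BREEDS
    n_per_breed: tuple[int, ...] = (11, 19, 12)
    n_markers: int = 5000
    n_chromosomes: int = 5
    drift_f: tuple[float, ...] = field(default_factory=drift_from_fst_targets)
    selected_locus: SelectedLocusSpec | None = field(
        default_factory=SelectedLocusSpec
    )
    ld_block: LdBlockSpec | None = None
    pheno: PhenoModelSpec = field(default_factory=PhenoModelSpec)
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    mean_spacing_bp: int = 72_500

    def __post_init__(self) -> None:
        if len(self.n_per_breed) != len(self.breeds):
            raise ValueError("n_per_breed must match breeds")
        if len(self.drift_f) != len(self.breeds):
            raise ValueError("drift_f must match breeds")
        if any(not (0 < f < 1) for f in self.drift_f):
            raise ValueError("drift_f values must lie in (0, 1)")
        if self.n_markers < 5:
            raise ValueError("n_markers must cover at least one scan window")


def association_config(seed: int = 0, n_horses: int = 400,
                       n_markers: int = 40) -> SimulationConfig:
    """Single-breed association-scale config with the 7-SNP LD block."""
    return SimulationConfig(
        seed=seed,
        breeds=(datasets.BREED_CT,),
        n_per_breed=(n_horses,),
        n_markers=n_markers,
        n_chromosomes=2,
        drift_f=(0.05,),
        selected_locus=None,
        ld_block=LdBlockSpec(),
    )


# ---------------------------------------------------------------------------
# genotype simulation


@dataclass
class PanelTruth:
    """Generator-side truth for a simulated panel."""

    ancestral_freq: np.ndarray  # background markers only
    breed_freqs: pd.DataFrame  # marker_id x breed true allele_b frequency
    selected_marker_ids: list[str]
    ld_block_marker_ids: list[str]
    focal_marker_id: str | None


def _seeded_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def simulate_panel_with_truth(
    config: SimulationConfig,
) -> tuple[GenotypePanel, PanelTruth]:
    """Simulate a genotype panel and return it with its generating truth."""
    rng = _seeded_rng(config.seed, 1)
    n_bg = config.n_markers
    lo, hi = config.ancestral_range
    ancestral = rng.uniform(lo, hi, size=n_bg)

    n_breeds = len(config.breeds)
    freqs = np.empty((n_breeds, n_bg))
    for i, f_drift in enumerate(config.drift_f):
        a = ancestral * (1.0 - f_drift) / f_drift
        b = (1.0 - ancestral) * (1.0 - f_drift) / f_drift
        freqs[i] = rng.beta(a, b)

    # marker map: background markers spread over numbered chromosomes
    per_chrom = np.full(config.n_chromosomes, n_bg // config.n_chromosomes)
    per_chrom[: n_bg % config.n_chromosomes] += 1
    chroms: list[str] = []
    positions: list[int] = []
    for c, n_c in enumerate(per_chrom, start=1):
        spacing = rng.integers(
            config.mean_spacing_bp // 3, config.mean_spacing_bp * 5 // 3,
            size=n_c,
        )
        pos = np.cumsum(spacing) + 10_000
        chroms.extend([str(c)] * n_c)
        positions.extend(int(p) for p in pos)

    markers = [
        MarkerInfo(f"snp_{c}_{p}", c, p, "A", "B")
        for c, p in zip(chroms, positions)
    ]

    selected_ids: list[str] = []
    if config.selected_locus is not None:
        sl = config.selected_locus
        if len(sl.freqs) != n_breeds:
            raise ValueError("selected-locus triplet must match breed count")
        on_chrom = [j for j, m in enumerate(markers)
                    if m.chromosome == sl.chromosome]
        if len(on_chrom) < sl.span:
            raise ValueError(
                f"chromosome {sl.chromosome} has too few markers for the "
                f"selected-locus span {sl.span}"
            )
        mid = len(on_chrom) // 2
        span_idx = on_chrom[mid - sl.span // 2: mid - sl.span // 2 + sl.span]
        for j in span_idx:
            freqs[:, j] = sl.freqs
            m = markers[j]
            markers[j] = MarkerInfo(
                m.marker_id, m.chromosome, m.position_bp,
                sl.allele_a, sl.allele_b,
            )
            selected_ids.append(m.marker_id)

    # background + implanted genotypes: HWE binomial within breed
    n_total = sum(config.n_per_breed)
    calls = np.empty((n_total, n_bg), dtype=np.int8)
    row = 0
    for i, n_i in enumerate(config.n_per_breed):
        calls[row: row + n_i] = rng.binomial(
            2, freqs[i][None, :], size=(n_i, n_bg)
        )
        row += n_i

    breed_freq_df = pd.DataFrame(
        freqs.T,
        index=pd.Index([m.marker_id for m in markers], name="marker_id"),
        columns=list(config.breeds),
    )

    # LD block: whole haplotypes drawn from the pool, appended as extra markers
    block_ids: list[str] = []
    focal_id: str | None = None
    if config.ld_block is not None:
        blk = config.ld_block
        site_alleles = blk.site_alleles()
        k = len(blk.positions)
        hap_mat = np.array(
            [[1 if h[s] == site_alleles[s][1] else 0 for s in range(k)]
             for h in blk.haplotypes]
        )
        pool_p = np.asarray(blk.frequencies) / np.sum(blk.frequencies)
        draws = rng.choice(len(blk.haplotypes), size=(n_total, 2), p=pool_p)
        block_calls = (hap_mat[draws[:, 0]] + hap_mat[draws[:, 1]]).astype(np.int8)
        block_markers = [
            MarkerInfo(f"snp_{blk.chromosome}_{p}", blk.chromosome, int(p),
                       site_alleles[s][0], site_alleles[s][1])
            for s, p in enumerate(blk.positions)
        ]
        block_ids = [m.marker_id for m in block_markers]
        focal_id = block_ids[blk.focal_index]
        markers = markers + block_markers
        calls = np.hstack([calls, block_calls])
        block_freq = hap_mat.T @ pool_p
        blk_df = pd.DataFrame(
            np.tile(block_freq[:, None], (1, n_breeds)),
            index=pd.Index(block_ids, name="marker_id"),
            columns=list(config.breeds),
        )
        breed_freq_df = pd.concat([breed_freq_df, blk_df])
    elif selected_ids:
        focal_id = selected_ids[len(selected_ids) // 2]

    sample_ids = []
    breeds = []
    for breed, n_i in zip(config.breeds, config.n_per_breed):
        for s in range(n_i):
            sample_ids.append(f"{breed}_{s + 1:03d}")
            breeds.append(breed)

    panel = GenotypePanel(markers, sample_ids, breeds, calls).sort_markers()
    truth = PanelTruth(
        ancestral_freq=ancestral,
        breed_freqs=breed_freq_df,
        selected_marker_ids=selected_ids,
        ld_block_marker_ids=block_ids,
        focal_marker_id=config.pheno.focal_marker_id or focal_id,
    )
    return panel, truth


def simulate_panel(config: SimulationConfig) -> GenotypePanel:
    """Simulate a genotype panel (see :func:`simulate_panel_with_truth`)."""
    return simulate_panel_with_truth(config)[0]


def true_pairwise_mean_fst(
    truth: PanelTruth, pair: tuple[str, str], background_only: bool = True
) -> float:
    """Genome-wide mean Wright Fst from the generator's true breed frequencies."""
    df = truth.breed_freqs
    if background_only:
        drop = set(truth.selected_marker_ids) | set(truth.ld_block_marker_ids)
        df = df.loc[[m for m in df.index if m not in drop]]
    fst = wright_fst(df[pair[0]].to_numpy(), df[pair[1]].to_numpy())
    return float(np.mean(fst))


# ---------------------------------------------------------------------------
# phenotype simulation


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_phenotypes(
    panel: GenotypePanel, config: SimulationConfig,
    focal_marker_id: str | None = None,
) -> pd.DataFrame:
    """Simulate race records for every horse in the panel.

    A standardised latent performance score per trait carries the covariate
    effects plus the recessive penalty for ``allele_a`` homozygotes at the
    focal marker; each trait is the inverse transform of its latent scale
    (earnings floored at zero, counts at least one start, times above the
    68.2 s/km floor).  Time records get per-trait missingness; Norwegian
    horses' earnings are recorded in NOK at the 0.95 exchange rate.
    """
    p = config.pheno
    if focal_marker_id is None:
        focal_marker_id = p.focal_marker_id
    if focal_marker_id is None:
        _, truth = simulate_panel_with_truth(config)
        focal_marker_id = truth.focal_marker_id
    if focal_marker_id is None:
        raise ValueError("no focal marker: set focal_marker_id or an implant")

    rng = _seeded_rng(config.seed, 2)
    n = panel.n_samples
    j = panel.marker_index(focal_marker_id)
    dosage = panel.calls[:, j].astype(float)
    marker = panel.markers[j]
    geno_strings = {
        0: marker.allele_a * 2,
        1: "".join(sorted(marker.allele_a + marker.allele_b)),
        2: marker.allele_b * 2,
    }
    genotype = np.array([geno_strings.get(int(d), "NN") for d in dosage])
    penalized = (dosage == 0).astype(float)  # homozygous allele_a

    sex = rng.choice(["mare", "gelding", "stallion"], size=n,
                     p=[0.5, 0.35, 0.15])
    age = rng.integers(6, 16, size=n)
    country = rng.choice(["SE", "NO"], size=n,
                         p=[1.0 - p.p_country_no, p.p_country_no])
    a = p.dmrt3_a_freq
    dmrt3 = rng.choice(["AA", "CA", "CC"], size=n,
                       p=[a * a, 2 * a * (1 - a), (1 - a) ** 2])

    sex_eff = dict(zip(["mare", "gelding", "stallion"], p.sex_effects))
    dmrt3_eff = dict(zip(["AA", "CA", "CC"], p.dmrt3_effects))
    cov = (
        np.array([sex_eff[s] for s in sex])
        + p.age_effect * (age - 10)
        + np.where(country == "NO", p.country_effect_no, 0.0)
        + np.array([dmrt3_eff[d] for d in dmrt3])
    )
    g = p.genotype_effect * penalized

    def latent(extra_sd: float = 1.0) -> np.ndarray:
        return cov + g + rng.normal(0.0, extra_sd, size=n)

    y_starts = p.starts_intercept + p.starts_scale * latent()
    n_starts = np.clip(np.round(10.0 ** y_starts - 1.0), 1, 300).astype(int)

    p_win = _invlogit(-2.3 + 0.5 * latent())
    n_wins = rng.binomial(n_starts, p_win)
    p_extra = _invlogit(-1.2 + 0.5 * latent())
    n_placings = n_wins + rng.binomial(n_starts - n_wins, p_extra)

    y_earn = p.earnings_intercept + p.earnings_scale * latent()
    earnings_sek = np.maximum(np.exp(y_earn) - 1000.0, 0.0)

    y_volt = p.time_volt_intercept + p.time_scale * (-(cov + g)
                                                     + rng.normal(size=n))
    time_volt = 68.2 + np.exp(y_volt)
    y_auto = p.time_auto_intercept + p.time_scale * (-(cov + g)
                                                     + rng.normal(size=n))
    time_auto = 68.2 + np.exp(y_auto)
    time_volt[rng.random(n) < p.p_missing_time_volt] = np.nan
    time_auto[rng.random(n) < p.p_missing_time_auto] = np.nan

    currency = np.where(country == "NO", "NOK", "SEK")
    earnings = np.where(currency == "NOK",
                        earnings_sek / 0.95, earnings_sek).round(2)

    return pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "sex": sex,
            "age": age,
            "country": country,
            "n_starts": n_starts,
            "n_wins": n_wins,
            "n_placings": n_placings,
            "win_freq": (n_wins / n_starts).round(6),
            "placing_freq": (n_placings / n_starts).round(6),
            "earnings": earnings,
            "currency": currency,
            "earnings_per_start": (earnings / n_starts).round(2),
            "time_volt": time_volt.round(2),
            "time_auto": time_auto.round(2),
            "dmrt3": dmrt3,
            "genotype": genotype,
        }
    )


# ---------------------------------------------------------------------------
# fixtures on disk


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def config_from_yaml(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key, cls in (("selected_locus", SelectedLocusSpec),
                     ("ld_block", LdBlockSpec)):
        if raw.get(key) is not None:
            spec = {k: tuple(v) if isinstance(v, list) else v
                    for k, v in raw[key].items()}
            raw[key] = cls(**spec)
    if raw.get("pheno") is not None:
        spec = {k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["pheno"].items()}
        raw["pheno"] = PhenoModelSpec(**spec)
    for key in ("breeds", "n_per_breed", "drift_f", "ancestral_range"):
        if isinstance(raw.get(key), list):
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)


def write_fixture(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic dataset and its truth manifest.

    Emits PED/MAP, the sample->breed TSV, the phenotype TSV and a JSON
    manifest recording the seed, config and generator truths.  Re-running
    with the same config is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, truth = simulate_panel_with_truth(config)
    phenos = simulate_phenotypes(panel, config,
                                 focal_marker_id=truth.focal_marker_id)

    paths = {
        "ped": out / "panel.ped",
        "map": out / "panel.map",
        "breeds": out / "breeds.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "manifest": out / "manifest.json",
    }
    write_ped_map(panel, paths["ped"], paths["map"])
    write_breed_tsv(panel, paths["breeds"])
    phenos.to_csv(paths["phenotypes"], sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "truth": {
            "selected_marker_ids": truth.selected_marker_ids,
            "ld_block_marker_ids": truth.ld_block_marker_ids,
            "focal_marker_id": truth.focal_marker_id,
            "mean_true_fst": {
                f"{b1}|{b2}": true_pairwise_mean_fst(truth, (b1, b2))
                for i, b1 in enumerate(config.breeds)
                for b2 in config.breeds[i + 1:]
            },
        },
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
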