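"""Synthetic study generator: weather, pig population, genotypes and RFID pings.

Everything downstream — day classification, trait derivation, marker QC, the
Bayes-C sampler, window decomposition — is exercised against data from this
module, whose ground truth (planted QTL, true genetic values, realized
heritability) is recorded in a :class:`TruthSet`.

The generative model mirrors the analysed structure of the real study:

* a two-generation pedigree of three sire breeds (Duroc, Landrace,
  Yorkshire) x two sexes, housed in grow-finish groups of six pens;
* gene-dropped SNP genotypes (founder allele frequencies uniform on a MAF
  range, Mendelian transmission, no linkage) on a multi-chromosome map;
* daily ping counts drawn from a negative binomial whose mean is a breed x
  sex x THI-category baseline (defaults are the study's observed cell
  means) plus a permanent animal effect and a genetic heat-response value
  acting through the ordered category contrast Normal=0 ... Emergency=3 —
  so the pairwise difference traits carry the planted genetic signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import phenotype
from .thi import CATEGORIES, CATEGORY_CONTRAST, THRESHOLDS_C

logger = logging.getLogger(__name__)

#: Mean daily pings per sire breed x sex x THI category (Normal, Alert,
#: Danger, Emergency), matching observed cell means in a US grow-finish herd.
DEFAULT_BASELINE_PINGS: dict[tuple[str, str], tuple[float, ...]] = {
    ("Duroc", "barrow"): (154.8, 179.0, 183.5, 194.3),
    ("Duroc", "gilt"): (152.0, 159.1, 162.1, 171.1),
    ("Yorkshire", "barrow"): (156.5, 160.5, 170.7, 188.4),
    ("Yorkshire", "gilt"): (130.9, 135.5, 137.5, 137.2),
    ("Landrace", "barrow"): (140.3, 131.7, 118.0, 71.2),
    ("Landrace", "gilt"): (129.3, 115.6, 101.7, 62.4),
}

DEFAULT_DAYS_PER_CATEGORY: dict[str, int] = {
    "Normal": 60, "Alert": 25, "Danger": 20, "Emergency": 15,
}


@dataclass
class ClimateProfile:
    """Sinusoidal daily/seasonal temperature and humidity trajectories."""

    t_mean: float = 22.0
    t_season_amp: float = 8.0
    t_daily_amp: float = 6.0
    rh_mean: float = 60.0
    rh_season_amp: float = 10.0
    rh_daily_amp: float = 10.0
    season_period_days: float = 365.0
    t_noise_sd: float = 1.0
    rh_noise_sd: float = 3.0

    @classmethod
    def constant(cls, temp_c: float, rh_pct: float) -> "ClimateProfile":
        return cls(t_mean=temp_c, t_season_amp=0.0, t_daily_amp=0.0,
                   rh_mean=rh_pct, rh_season_amp=0.0, rh_daily_amp=0.0,
                   t_noise_sd=0.0, rh_noise_sd=0.0)


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic generator.

    Defaults emulate one grow-finish group of ~240 pigs in six pens, three
    sire breeds, a reduced-scale multi-chromosome marker panel, and baseline
    feeding activity from the observed breed x sex x category cell means.
    ``var_genetic`` is the variance of the genetic heat-response effect (per
    unit of category contrast); if left ``None`` it is calibrated so the
    calibration pair's trait reaches ``target_h2``.
    """

    n_animals: int = 240
    n_groups: int = 1
    n_pens_per_group: int = 6
    breed_labels: tuple[str, ...] = ("Duroc", "Landrace", "Yorkshire")
    n_chromosomes: int = 5
    n_snps: int = 1000
    chrom_length_bp: int = 20_000_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_qtl: int = 10
    var_genetic: float | None = None
    target_h2: float = 0.15
    var_animal: float = 100.0
    dispersion: float = 30.0
    baseline_pings: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_PINGS))
    n_days_per_category: dict = field(default_factory=lambda: dict(DEFAULT_DAYS_PER_CATEGORY))
    category_dropout: float = 0.10
    litter_size: int = 6
    litters_per_sire: int = 4
    calibration_pair: tuple[str, str] = ("Normal", "Alert")
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.var_genetic is not None and self.var_genetic < 0:
            raise ValueError("var_genetic must be >= 0")
        if self.var_animal < 0 or self.dispersion <= 0:
            raise ValueError("var_animal must be >= 0 and dispersion > 0")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl must not exceed n_snps")
        if self.n_snps < self.n_chromosomes:
            raise ValueError("n_snps must be >= n_chromosomes")
        if any(v <= 0 for row in self.baseline_pings.values() for v in row):
            raise ValueError("baseline_pings must be strictly positive")
        if not (0 <= self.category_dropout < 1):
            raise ValueError("category_dropout must lie in [0, 1)")
        if self.n_animals < 0:
            raise ValueError("n_animals must be >= 0")


@dataclass
class TruthSet:
    """Ground truth recorded by the generator for parameter-recovery tests."""

    qtl_ids: list
    qtl_effects: np.ndarray
    genetic_values: pd.Series         # per study animal
    target_h2: float
    realized_h2: float


# ----------------------------------------------------------------------
# weather


def simulate_weather(
    n_days: int,
    profile: ClimateProfile | None = None,
    seed: int = 0,
    start_date: str = "2015-06-01",
) -> pd.DataFrame:
    """Hourly weather records: 24 rows per day, RH clipped to [0, 100]."""
    if n_days < 0:
        raise ValueError("n_days must be >= 0")
    if profile is None:
        profile = ClimateProfile()
    cols = ["timestamp", "temp_c", "rh_pct"]
    if n_days == 0:
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng([seed, 101])
    ts = pd.date_range(start=start_date, periods=24 * n_days, freq="h")
    day = np.repeat(np.arange(n_days), 24)
    hour = np.tile(np.arange(24), n_days)
    season = np.sin(2 * np.pi * day / profile.season_period_days)
    diurnal = np.sin(2 * np.pi * (hour - 9) / 24.0)      # peaks mid-afternoon
    t = (profile.t_mean + profile.t_season_amp * season
         + profile.t_daily_amp * diurnal
         + rng.normal(0.0, profile.t_noise_sd, len(day)))
    rh = (profile.rh_mean + profile.rh_season_amp * season
          - profile.rh_daily_amp * diurnal
          + rng.normal(0.0, profile.rh_noise_sd, len(day)))
    return pd.DataFrame({
        "timestamp": ts, "temp_c": t, "rh_pct": np.clip(rh, 0.0, 100.0),
    })


def make_day_classes(
    n_days_per_category: dict[str, int] | None = None,
    start_date: str = "2015-06-01",
) -> pd.DataFrame:
    """Synthetic day classification with prescribed category counts.

    Categories are interleaved over consecutive dates; the max-THI column
    carries a representative value inside each category's interval.
    """
    if n_days_per_category is None:
        n_days_per_category = dict(DEFAULT_DAYS_PER_CATEGORY)
    rep_thi = {
        "Normal": 20.0,
        "Alert": (THRESHOLDS_C[0] + THRESHOLDS_C[1]) / 2,
        "Danger": (THRESHOLDS_C[1] + THRESHOLDS_C[2]) / 2,
        "Emergency": THRESHOLDS_C[2] + 1.5,
    }
    seq: list[str] = []
    remaining = {c: int(n_days_per_category.get(c, 0)) for c in CATEGORIES}
    while any(v > 0 for v in remaining.values()):
        for c in CATEGORIES:
            if remaining[c] > 0:
                seq.append(c)
                remaining[c] -= 1
    dates = pd.date_range(start=start_date, periods=len(seq), freq="D").date
    return pd.DataFrame({
        "date": dates,
        "max_thi_c": [rep_thi[c] for c in seq],
        "category": seq,
    })


# ----------------------------------------------------------------------
# population and genotypes


def simulate_population(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-generation pedigree with full- and half-sib families.

    Litters of ``cfg.litter_size`` cycle through the sire breeds; each sire
    serves ``cfg.litters_per_sire`` litters (full-sibs within a litter,
    paternal half-sibs across a sire's litters).  Offspring are assigned
    round-robin to grow-finish groups and pens, so pen sizes are balanced;
    two farrowing groups alternate within each grow-finish group.

    Returns
    -------
    (meta, pedigree)
        ``meta``: one row per study animal with ``animal_id``, ``sire_breed``,
        ``sex``, ``grow_finish_group``, ``pen``, ``farrowing_group``,
        ``sire_id``, ``dam_id``.  ``pedigree``: all individuals with ``id``,
        ``sire``, ``dam`` ("0" for founders), parents listed first.
    """
    cfg.validate()
    breeds = tuple(cfg.breed_labels)
    if cfg.n_animals == 0:
        meta = pd.DataFrame(columns=[
            "animal_id", "sire_breed", "sex", "grow_finish_group",
            "pen", "farrowing_group", "sire_id", "dam_id",
        ])
        return meta, pd.DataFrame(columns=["id", "sire", "dam"])

    rng = np.random.default_rng([cfg.seed, 404])
    n_litters = -(-cfg.n_animals // cfg.litter_size)
    sire_of_litter, dam_of_litter, breed_of_litter = [], [], []
    sire_count = {b: 0 for b in breeds}
    sire_litters: dict[str, int] = {}
    current_sire = {b: None for b in breeds}
    for li in range(n_litters):
        b = breeds[li % len(breeds)]
        s = current_sire[b]
        if s is None or sire_litters[s] >= cfg.litters_per_sire:
            sire_count[b] += 1
            s = f"S_{b}_{sire_count[b]:03d}"
            sire_litters[s] = 0
            current_sire[b] = s
        sire_litters[s] += 1
        sire_of_litter.append(s)
        dam_of_litter.append(f"D_{li + 1:04d}")
        breed_of_litter.append(b)

    rows = []
    a = 0
    for li in range(n_litters):
        # balanced sexes within a litter, shuffled so sex is not tied to the
        # birth-order position (and hence not to the round-robin pen slot)
        half = cfg.litter_size // 2
        sexes = ["barrow"] * (cfg.litter_size - half) + ["gilt"] * half
        rng.shuffle(sexes)
        for o in range(cfg.litter_size):
            if a >= cfg.n_animals:
                break
            group = a % cfg.n_groups
            idx_in_group = a // cfg.n_groups
            pen = idx_in_group % cfg.n_pens_per_group
            rows.append({
                "animal_id": f"A{a + 1:05d}",
                "sire_breed": breed_of_litter[li],
                "sex": sexes[o],
                "grow_finish_group": f"g{group + 1}",
                "pen": f"p{pen + 1}",
                "farrowing_group": f"fg{group + 1}_{li % 2 + 1}",
                "sire_id": sire_of_litter[li],
                "dam_id": dam_of_litter[li],
            })
            a += 1
    meta = pd.DataFrame(rows)
    founders = sorted(set(meta["sire_id"])) + sorted(set(meta["dam_id"]))
    ped = pd.DataFrame({"id": founders, "sire": "0", "dam": "0"})
    kids = meta[["animal_id", "sire_id", "dam_id"]].rename(
        columns={"animal_id": "id", "sire_id": "sire", "dam_id": "dam"})
    return meta, pd.concat([ped, kids], ignore_index=True)


def _unique_positions(rng: np.random.Generator, k: int, upper: int) -> np.ndarray:
    pos: np.ndarray = np.unique(rng.integers(1, upper + 1, size=4 * k))
    while len(pos) < k:
        pos = np.unique(np.concatenate([pos, rng.integers(1, upper + 1, size=4 * k)]))
    return np.sort(rng.choice(pos, size=k, replace=False))


def simulate_genotypes(
    pedigree: pd.DataFrame, cfg: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-drop SNP genotypes down the pedigree.

    Founder haplotype alleles are Bernoulli draws at frequencies uniform on
    ``cfg.maf_range``; each offspring receives one allele per locus from each
    parent, independently across loci (no linkage).  Dosages are in {0,1,2}.

    Returns
    -------
    (dosages, marker_map)
        ``dosages``: individuals x markers DataFrame (all pedigree members);
        ``marker_map``: ``marker_id``, ``chromosome``, ``position_bp`` with
        unique positions per chromosome.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 202])
    m = cfg.n_snps
    per_chrom = np.full(cfg.n_chromosomes, m // cfg.n_chromosomes)
    per_chrom[: m % cfg.n_chromosomes] += 1
    recs = []
    j = 0
    for c in range(cfg.n_chromosomes):
        pos = _unique_positions(rng, int(per_chrom[c]), cfg.chrom_length_bp)
        for p_ in pos:
            recs.append({"marker_id": f"snp{j:05d}", "chromosome": str(c + 1),
                         "position_bp": int(p_)})
            j += 1
    marker_map = pd.DataFrame(recs)

    freq = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    haplo: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for _, row in pedigree.iterrows():
        if row["sire"] == "0":
            h1 = (rng.random(m) < freq).astype(np.int8)
            h2 = (rng.random(m) < freq).astype(np.int8)
        else:
            fh1, fh2 = haplo[row["sire"]]
            mh1, mh2 = haplo[row["dam"]]
            pick_f = rng.integers(0, 2, size=m)
            pick_m = rng.integers(0, 2, size=m)
            h1 = np.where(pick_f == 0, fh1, fh2).astype(np.int8)
            h2 = np.where(pick_m == 0, mh1, mh2).astype(np.int8)
        haplo[row["id"]] = (h1, h2)
    ids = list(pedigree["id"])
    dos = np.vstack([haplo[i][0] + haplo[i][1] for i in ids])
    dosages = pd.DataFrame(dos.astype(float), index=ids,
                           columns=marker_map["marker_id"])
    return dosages, marker_map


# ----------------------------------------------------------------------
# phenotype generation


def _mean_baseline(cfg: SimConfig, cat: str) -> float:
    ci = CATEGORIES.index(cat)
    return float(np.mean([row[ci] for row in cfg.baseline_pings.values()]))


def _day_variance(cfg: SimConfig, mu: float) -> float:
    return mu + mu * mu / cfg.dispersion


def calibrate_var_genetic(cfg: SimConfig, target_h2: float,
                          pair: tuple[str, str] | None = None) -> float:
    """Genetic variance giving the target heritability for the pairwise trait.

    Uses the analytic variance decomposition of the standardized difference
    trait z(A) - z(B): within category c, the between-animal variance of
    deviations is var_animal + var_genetic * contrast(c)^2 + sampling noise of
    the category mean; the genetic share of the trait follows from the
    z-scaling of each component.  Solved for var_genetic by root finding.
    """
    if pair is None:
        pair = cfg.calibration_pair
    ca, cb = (float(CATEGORY_CONTRAST[p]) for p in pair)
    parts = {}
    for p in pair:
        mu = _mean_baseline(cfg, p)
        n_days = cfg.n_days_per_category.get(p, 0)
        if n_days < 1:
            raise ValueError(f"calibration category {p!r} has no days")
        parts[p] = _day_variance(cfg, mu) / n_days

    def h2_of(vg: float) -> float:
        sa = np.sqrt(cfg.var_animal + vg * ca**2 + parts[pair[0]])
        sb = np.sqrt(cfg.var_animal + vg * cb**2 + parts[pair[1]])
        va = (1 / sa - 1 / sb) ** 2 * cfg.var_animal
        vgt = (ca / sa - cb / sb) ** 2 * vg
        noise = parts[pair[0]] / sa**2 + parts[pair[1]] / sb**2
        return vgt / (va + vgt + noise)

    if target_h2 <= 0:
        return 0.0
    hi = 1.0
    while h2_of(hi) < target_h2:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError(f"target_h2={target_h2} unattainable")
    return float(brentq(lambda v: h2_of(v) - target_h2, 0.0, hi, xtol=1e-10))


def plant_qtl_and_simulate_pings(
    dosages: pd.DataFrame,
    meta: pd.DataFrame,
    day_classes: pd.DataFrame,
    cfg: SimConfig,
) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate daily RFID ping counts with a planted genetic heat response.

    Daily count ~ NegativeBinomial(mean, dispersion) with
    mean = baseline[breed, sex, category] + permanent animal effect
    + genetic value x contrast(category); means are floored at 1.0 (logged)
    if effects drive them non-positive.  Each animal independently drops each
    THI category with probability ``cfg.category_dropout`` (tag-loss
    emulation).  The returned :class:`TruthSet` records the planted QTL, true
    genetic values and the heritability realized by the derived calibration
    pair trait (squared correlation between the trait and the true genetic
    values).
    """
    cfg.validate()
    cats_present = sorted(set(day_classes["category"]), key=CATEGORIES.index)
    if len(cats_present) < 2:
        raise ValueError("day_classes must cover at least 2 THI categories")
    rng = np.random.default_rng([cfg.seed, 303])

    animals = list(meta["animal_id"])
    Z = dosages.loc[animals].to_numpy(dtype=float)
    Zc = Z - Z.mean(axis=0)
    m = Z.shape[1]
    var_genetic = cfg.var_genetic
    if var_genetic is None:
        var_genetic = calibrate_var_genetic(cfg, cfg.target_h2)
    qtl_idx = np.sort(rng.choice(m, size=cfg.n_qtl, replace=False))
    eff = rng.normal(size=cfg.n_qtl)
    g_raw = Zc[:, qtl_idx] @ eff
    v_raw = float(np.var(g_raw, ddof=1)) if len(animals) > 1 else 0.0
    scale = np.sqrt(var_genetic / v_raw) if (v_raw > 0 and var_genetic > 0) else 0.0
    g = g_raw * scale
    eff = eff * scale
    a_perm = rng.normal(0.0, np.sqrt(cfg.var_animal), size=len(animals))

    dates_by_cat = {c: day_classes.loc[day_classes["category"] == c, "date"].to_numpy()
                    for c in cats_present}
    n_clamped = 0
    rec_animal, rec_date, rec_pings = [], [], []
    for i, aid in enumerate(animals):
        breed = meta.iloc[i]["sire_breed"]
        sex = meta.iloc[i]["sex"]
        base_row = cfg.baseline_pings[(breed, sex)]
        kept = [c for c in cats_present if rng.random() >= cfg.category_dropout]
        if not kept:
            kept = [cats_present[int(rng.integers(len(cats_present)))]]
        for c in kept:
            mu = base_row[CATEGORIES.index(c)] + a_perm[i] + g[i] * CATEGORY_CONTRAST[c]
            if mu <= 0:
                n_clamped += 1
                mu = 1.0
            dts = dates_by_cat[c]
            p_nb = cfg.dispersion / (cfg.dispersion + mu)
            counts = rng.negative_binomial(cfg.dispersion, p_nb, size=len(dts))
            rec_animal.extend([aid] * len(dts))
            rec_date.extend(dts)
            rec_pings.extend(counts.tolist())
    if n_clamped:
        logger.info("clamped %d non-positive daily means to 1.0", n_clamped)
    pings = pd.DataFrame({"animal_id": rec_animal, "date": rec_date,
                          "pings": np.asarray(rec_pings, dtype=int)})

    g_series = pd.Series(g, index=animals, name="genetic_value")
    realized = _realized_h2(pings, day_classes, meta, g_series, cfg.calibration_pair)
    truth = TruthSet(
        qtl_ids=[dosages.columns[j] for j in qtl_idx],
        qtl_effects=eff,
        genetic_values=g_series,
        target_h2=float(cfg.target_h2) if cfg.var_genetic is None else float("nan"),
        realized_h2=realized,
    )
    return pings, truth


def _realized_h2(pings, day_classes, meta, g_series, pair) -> float:
    """Squared correlation of the derived pair trait with true genetic values."""
    if float(np.var(g_series.to_numpy())) == 0.0:
        return 0.0
    prof = phenotype.category_profile(pings, day_classes)
    z = phenotype.standardize_deviations(prof, meta)
    traits = phenotype.pairwise_traits(z)
    name = f"{pair[0]}-{pair[1]}"
    t = traits[name].dropna()
    if len(t) < 3:
        return float("nan")
    gg = g_series.loc[t.index].to_numpy()
    if np.var(gg) == 0.0:
        return 0.0
    r = np.corrcoef(t.to_numpy(), gg)[0, 1]
    return float(r * r)


@dataclass
class SimulationResult:
    """Bundle of everything one synthetic study produces."""

    meta: pd.DataFrame
    pedigree: pd.DataFrame
    dosages: pd.DataFrame          # study animals x markers
    marker_map: pd.DataFrame
    day_classes: pd.DataFrame
    pings: pd.DataFrame
    truth: TruthSet
    weather: pd.DataFrame | None = None


def simulate_all(cfg: SimConfig, with_weather: bool = False) -> SimulationResult:
    """Run the full generator: population, genotypes, day classes, pings."""
    cfg.validate()
    meta, ped = simulate_population(cfg)
    dosages_all, marker_map = simulate_genotypes(ped, cfg)
    dosages = dosages_all.loc[meta["animal_id"]]
    days = make_day_classes(cfg.n_days_per_category)
    pings, truth = plant_qtl_and_simulate_pings(dosages, meta, days, cfg)
    weather = None
    if with_weather:
        weather = simulate_weather(sum(cfg.n_days_per_category.values()), seed=cfg.seed)
    return SimulationResult(meta=meta, pedigree=ped, dosages=dosages,
                            marker_map=marker_map, day_classes=days,
                            pings=pings, truth=truth, weather=weather)
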