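"""Bayes-C / Bayes-Cpi whole-genome regression, heritability and 1-Mb windows.

The trait model is y = X beta + Z u + e: X carries the fixed effects
(intercept, sex, sire breed, contemporary group = farrowing group x pen),
Z the column-centered SNP dosages.  Each marker effect is zero with
probability pi and otherwise drawn from N(0, sigma2_u) with a common
variance (Bayes-C); Bayes-Cpi additionally samples pi under a uniform
prior.  Heritability per posterior sample is var(Zu) / (var(Zu) + sigma2_e)
with the variance taken across animals; its reported uncertainty is the SD
of the final 100 saved samples.  Genomic variance is decomposed into
non-overlapping 1-Mb windows (window index = floor(bp / 1e6)): per saved
sample the share of var(Zu) attributable to the window's markers is
computed, and the posterior mean share (as a percent) is reported per
window.  Windows above 1% are "reported", above 3% "top"; runs of adjacent
above-threshold windows are pruned to the single window with the greatest
share before gene-list construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from . import _gibbs

logger = logging.getLogger(__name__)

__all__ = [
    "ChainConfig",
    "GwasDesign",
    "PosteriorSamples",
    "BayesCRegressor",
    "build_design",
    "run_bayes_c",
    "run_bayes_cpi",
    "summarize_heritability",
    "window_variance",
    "merge_adjacent",
]


@dataclass
class ChainConfig:
    """MCMC settings for one Bayes-C / Bayes-Cpi run.

    ``pi`` is either a fixed fraction in [0, 1] (Bayes-C) or the string
    ``"estimate"`` (Bayes-Cpi).  Defaults follow the long Bayes-C protocol:
    41,000 iterations, 1000 burn-in, thinning every 40 (1000 saved states).
    Prior variances are on the genomic/residual variance scale; the prior pi
    used to initialise a Bayes-Cpi chain is 0.98.
    """

    n_iter: int = 41_000
    burn_in: int = 1_000
    thin: int = 40
    pi: float | str = 0.99
    prior_pi: float = 0.98
    prior_var_genetic: float = 0.10
    prior_var_residual: float = 0.10
    df_genetic: float = 4.0
    df_residual: float = 4.0
    fix_variances: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.thin and self.burn_in < self.n_iter):
            raise ValueError("require burn_in < n_iter and thin >= 1")
        if isinstance(self.pi, str) and self.pi != "estimate":
            raise ValueError("pi must be a fraction in [0, 1] or 'estimate'")
        if not isinstance(self.pi, str) and not (0.0 <= self.pi <= 1.0):
            raise ValueError("pi must lie in [0, 1]")


@dataclass
class GwasDesign:
    """Aligned design for one pairwise-THI trait."""

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray                       # column-centered dosages
    animal_ids: list
    marker_ids: list
    fixed_effect_names: list
    allele_freq: np.ndarray             # per-marker allele frequency (pre-centering)


@dataclass
class PosteriorSamples:
    """Saved MCMC states and derived summaries for one chain."""

    sigma2_u: np.ndarray                # per-marker effect variance draws
    sigma2_e: np.ndarray
    pi: np.ndarray
    genomic_var: np.ndarray             # var over animals of Zu, per saved state
    h2: np.ndarray
    effects: np.ndarray                 # (n_saved, n_markers)
    indicators: np.ndarray              # (n_saved, n_markers) uint8
    beta: np.ndarray                    # (n_saved, n_fixed)
    pi_trace: np.ndarray                # per-iteration pi (convergence plotting)
    marker_ids: list
    animal_ids: list = field(default_factory=list)
    Z: np.ndarray | None = None         # centered dosages, kept for window analysis

    @property
    def n_saved(self) -> int:
        return len(self.h2)

    @property
    def inclusion_freq(self) -> np.ndarray:
        """Posterior inclusion frequency per marker."""
        return self.indicators.mean(axis=0)

    @property
    def mean_effect(self) -> np.ndarray:
        """Posterior mean marker effect (zeros included)."""
        return self.effects.mean(axis=0)

    def marker_summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker_id": self.marker_ids,
            "inclusion_freq": self.inclusion_freq,
            "mean_effect": self.mean_effect,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sigma2_u": self.sigma2_u,
            "sigma2_e": self.sigma2_e,
            "pi": self.pi,
            "genomic_var": self.genomic_var,
            "h2": self.h2,
        })


class SamplerError(RuntimeError):
    """Raised when the Gibbs chain hits a non-finite state."""


class BayesCRegressor(RegressorMixin, BaseEstimator):
    """Bayes-C / Bayes-Cpi whole-genome regression estimator.

    Scikit-learn style: ``fit(X, y, covariates=...)`` where ``X`` is the
    animals x markers dosage matrix (raw {0,1,2} or continuous imputed;
    centered internally) and ``covariates`` an optional fixed-effect design
    (an intercept column is used when omitted).

    Parameters
    ----------
    pi : float or "estimate"
        Prior probability that a marker has no effect; ``"estimate"``
        samples pi (Bayes-Cpi).
    n_iter, burn_in, thin : int
        Chain length, burn-in, thinning of saved states.
    prior_var_genetic, prior_var_residual : float
        Prior genomic and residual variances; the genomic prior is converted
        to a per-marker effect-variance scale by dividing by
        (1 - pi) * sum_j 2 p_j (1 - p_j), i.e. it is spread over the markers
        expected to carry effects.
    df_genetic, df_residual : float
        Degrees of freedom of the scaled-inverse-chi-square variance priors;
        the scale is set so the prior mode equals the supplied variance.
    fix_variances : bool
        Hold both variance components at their priors (df -> infinity limit);
        used for the ridge-equivalence check.
    pi_block, pi_tol, max_pi_blocks :
        Bayes-Cpi convergence: after the initial chain, extend in
        ``pi_block``-iteration blocks (at most ``max_pi_blocks``) until the
        split-half difference of the mean of sampled pi falls below
        ``pi_tol``.
    random_state : int
        Seed for the chain.

    Attributes
    ----------
    samples_ : PosteriorSamples
    coef_ : ndarray — posterior mean marker effects.
    inclusion_freq_ : ndarray — posterior inclusion frequency per marker.
    pi_ : float — posterior mean pi.
    h2_ : float — posterior mean heritability.
    h2_sd_last100_ : float — SD of the last 100 saved heritability states.
    """

    def __init__(
        self,
        pi: float | str = 0.99,
        n_iter: int = 41_000,
        burn_in: int = 1_000,
        thin: int = 40,
        prior_pi: float = 0.98,
        prior_var_genetic: float = 0.10,
        prior_var_residual: float = 0.10,
        df_genetic: float = 4.0,
        df_residual: float = 4.0,
        fix_variances: bool = False,
        pi_block: int = 8_000,
        pi_tol: float = 1e-4,
        max_pi_blocks: int = 4,
        random_state: int = 0,
    ):
        self.pi = pi
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.prior_pi = prior_pi
        self.prior_var_genetic = prior_var_genetic
        self.prior_var_residual = prior_var_residual
        self.df_genetic = df_genetic
        self.df_residual = df_residual
        self.fix_variances = fix_variances
        self.pi_block = pi_block
        self.pi_tol = pi_tol
        self.max_pi_blocks = max_pi_blocks
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y, covariates=None, allele_freq=None, marker_ids=None, animal_ids=None):
        Zraw = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        n, m = Zraw.shape
        if y.shape[0] != n:
            raise ValueError("X and y have inconsistent numbers of animals")
        if covariates is None:
            Xf = np.ones((n, 1))
            fixed_names = ["intercept"]
        else:
            Xf = np.asarray(covariates, dtype=np.float64)
            if Xf.ndim == 1:
                Xf = Xf[:, None]
            fixed_names = [f"fx{i}" for i in range(Xf.shape[1])]

        col_mean = Zraw.mean(axis=0)
        if allele_freq is None:
            allele_freq = col_mean / 2.0
        allele_freq = np.asarray(allele_freq, dtype=float)
        sum2pq = float(np.sum(2.0 * allele_freq * (1.0 - allele_freq)))
        if sum2pq <= 0:
            raise ValueError("all markers are monomorphic: sum 2p(1-p) is zero")
        Zc = Zraw - col_mean

        estimate_pi = isinstance(self.pi, str) and self.pi == "estimate"
        pi0 = self.prior_pi if estimate_pi else float(self.pi)

        nu_u, nu_e = float(self.df_genetic), float(self.df_residual)
        # the prior genomic variance is spread over the markers expected to be
        # included: per-marker scale = var_g / ((1 - pi) * sum 2p(1-p)); the
        # kernel rescales with the current pi as a Bayes-Cpi chain moves
        incl_frac = max(1.0 - pi0, 1.0 / m)
        self._max_incl_frac = incl_frac
        per_marker_var = self.prior_var_genetic / (incl_frac * sum2pq)
        # prior mode of scaled-inv-chi2(nu, s2) is nu*s2/(nu+2); match it to the prior variance
        scale_u_base = (self.prior_var_genetic / sum2pq) * (nu_u + 2.0) / nu_u
        scale_e = self.prior_var_residual * (nu_e + 2.0) / nu_e

        s2u0 = per_marker_var
        s2e0 = self.prior_var_residual

        u = np.zeros(m)
        beta = np.zeros(Xf.shape[1])
        n_iter0 = self.n_iter
        blocks = self._run_blocks(np.asfortranarray(Zc), y, np.asfortranarray(Xf),
                                  u, beta, s2u0, s2e0, pi0,
                                  n_iter0, estimate_pi,
                                  nu_u, scale_u_base, nu_e, scale_e)
        samples = blocks
        samples.marker_ids = list(marker_ids) if marker_ids is not None else [f"m{j}" for j in range(m)]
        samples.animal_ids = list(animal_ids) if animal_ids is not None else list(range(n))
        samples.Z = Zc

        self.samples_ = samples
        self.coef_ = samples.mean_effect
        self.inclusion_freq_ = samples.inclusion_freq
        self.pi_ = float(samples.pi.mean())
        self.h2_ = float(samples.h2.mean())
        tail = samples.h2[-100:]
        self.h2_sd_last100_ = float(np.std(tail, ddof=1)) if len(tail) >= 2 else 0.0
        self.beta_mean_ = samples.beta.mean(axis=0)
        self.X_mean_ = col_mean
        self.fixed_mean_ = float((Xf @ self.beta_mean_).mean())
        self.n_features_in_ = m
        self.fixed_effect_names_ = fixed_names
        return self

    def _run_blocks(self, Zc, y, Xf, u, beta, s2u, s2e, pi,
                    n_iter, estimate_pi, nu_u, scale_u_base, nu_e, scale_e) -> PosteriorSamples:
        """Run the kernel, extending Bayes-Cpi chains until the pi estimate settles."""
        m = Zc.shape[1]
        p = Xf.shape[1]
        parts = []
        pi_traces = []
        seed = int(self.random_state) % (2**31)

        def one_block(n_it, burn, seed_off):
            n_saved = (n_it - burn) // self.thin
            out = {
                "s2u": np.empty(n_saved), "s2e": np.empty(n_saved),
                "pi": np.empty(n_saved), "gv": np.empty(n_saved), "h2": np.empty(n_saved),
                "u": np.empty((n_saved, m)), "delta": np.empty((n_saved, m), dtype=np.uint8),
                "beta": np.empty((n_saved, p)), "trace": np.empty(n_it),
            }
            status, it, s, s2u_f, s2e_f, pi_f = _gibbs.run_chain(
                Zc, y, Xf, u, beta, s2u, s2e, pi,
                n_it, burn, self.thin, estimate_pi, self.fix_variances,
                nu_u, scale_u_base, self._max_incl_frac, nu_e, scale_e,
                (seed + seed_off) % (2**31),
                out["s2u"], out["s2e"], out["pi"], out["gv"], out["h2"],
                out["u"], out["delta"], out["beta"], out["trace"],
            )
            if status != _gibbs.OK:
                raise SamplerError(f"non-finite sampler state at iteration {it}")
            return out, s, s2u_f, s2e_f, pi_f

        out, s, s2u, s2e, pi = one_block(n_iter, self.burn_in, 0)
        parts.append({k: v[:s] if k != "trace" else v for k, v in out.items()})
        pi_traces.append(out["trace"])

        if estimate_pi:
            for block in range(1, self.max_pi_blocks + 1):
                pis = np.concatenate([p_["pi"] for p_ in parts])
                half = len(pis) // 2
                if half >= 1 and abs(pis[:half].mean() - pis[half:].mean()) < self.pi_tol:
                    break
                logger.info("extending Bayes-Cpi chain by %d iterations (block %d)",
                            self.pi_block, block)
                out, s, s2u, s2e, pi = one_block(self.pi_block, 0, block)
                parts.append({k: v[:s] if k != "trace" else v for k, v in out.items()})
                pi_traces.append(out["trace"])

        return PosteriorSamples(
            sigma2_u=np.concatenate([p_["s2u"] for p_ in parts]),
            sigma2_e=np.concatenate([p_["s2e"] for p_ in parts]),
            pi=np.concatenate([p_["pi"] for p_ in parts]),
            genomic_var=np.concatenate([p_["gv"] for p_ in parts]),
            h2=np.concatenate([p_["h2"] for p_ in parts]),
            effects=np.concatenate([p_["u"] for p_ in parts]),
            indicators=np.concatenate([p_["delta"] for p_ in parts]),
            beta=np.concatenate([p_["beta"] for p_ in parts]),
            pi_trace=np.concatenate(pi_traces),
            marker_ids=[],
        )

    def predict(self, X, covariates=None):
        Z = np.asarray(X, dtype=float) - self.X_mean_
        g = Z @ self.coef_
        if covariates is None:
            return g + self.fixed_mean_
        return g + np.asarray(covariates, dtype=float) @ self.beta_mean_


# ----------------------------------------------------------------------
# design construction and module-level operation wrappers


def build_design(
    traits: pd.DataFrame,
    trait_name: str,
    meta: pd.DataFrame,
    dosages: pd.DataFrame,
    marker_map: pd.DataFrame | None = None,
) -> GwasDesign:
    """Assemble y, X and centered Z for one pairwise-THI trait.

    Fixed effects are an intercept plus dummy-coded sex, sire breed and
    contemporary group (farrowing group x pen) with the first level of each
    factor dropped.  Animals missing the trait, metadata or genotypes are
    excluded; Z columns are centered on the retained animals.
    """
    meta = meta.set_index("animal_id") if "animal_id" in meta.columns else meta
    tr = traits[trait_name].dropna()
    animals = [a for a in tr.index if a in meta.index and a in dosages.index]
    if len(animals) == 0:
        raise ValueError(f"no animals with trait {trait_name!r}, metadata and genotypes")
    y = tr.loc[animals].to_numpy(dtype=float)
    sub = meta.loc[animals]
    cg = sub["farrowing_group"].astype(str) + ":" + sub["pen"].astype(str)
    small = cg.value_counts()
    if (small < 2).any():
        warnings.warn(
            f"{int((small < 2).sum())} contemporary-group cell(s) with < 2 animals (retained)",
            UserWarning, stacklevel=2,
        )
    fx = pd.DataFrame({
        "sex": sub["sex"].astype(str),
        "sire_breed": sub["sire_breed"].astype(str),
        "cg": cg,
    }, index=sub.index)
    dummies = pd.get_dummies(fx, drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(animals)), dummies.to_numpy()])
    names = ["intercept"] + list(dummies.columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient after reference-level dropping")

    if marker_map is not None:
        order = [mk for mk in marker_map["marker_id"] if mk in dosages.columns]
    else:
        order = list(dosages.columns)
    Zraw = dosages.loc[animals, order].to_numpy(dtype=float)
    freq = Zraw.mean(axis=0) / 2.0
    Zc = Zraw - Zraw.mean(axis=0)
    return GwasDesign(
        y=y, X=X, Z=Zc, animal_ids=list(animals), marker_ids=order,
        fixed_effect_names=names, allele_freq=freq,
    )


def _estimator_from_config(cfg: ChainConfig, estimate_pi: bool) -> BayesCRegressor:
    return BayesCRegressor(
        pi="estimate" if estimate_pi else cfg.pi,
        n_iter=cfg.n_iter, burn_in=cfg.burn_in, thin=cfg.thin,
        prior_pi=cfg.prior_pi,
        prior_var_genetic=cfg.prior_var_genetic,
        prior_var_residual=cfg.prior_var_residual,
        df_genetic=cfg.df_genetic, df_residual=cfg.df_residual,
        fix_variances=cfg.fix_variances, random_state=cfg.seed,
    )


def _fit_design(est: BayesCRegressor, design: GwasDesign) -> PosteriorSamples:
    est.fit(
        design.Z + 0.0, design.y, covariates=design.X,
        allele_freq=design.allele_freq,
        marker_ids=design.marker_ids, animal_ids=design.animal_ids,
    )
    # design.Z is already centered; re-centering inside fit is a no-op
    return est.samples_


def run_bayes_cpi(design: GwasDesign, cfg: ChainConfig | None = None) -> PosteriorSamples:
    """Bayes-Cpi: sample pi alongside effects and variances.

    Runs at least 8100 iterations (100 burn-in) and extends in 8000-iteration
    blocks until the split-half difference of the mean sampled pi is < 1e-4.
    """
    if cfg is None:
        cfg = ChainConfig(n_iter=8_100, burn_in=100, thin=1, pi="estimate")
    if cfg.pi != "estimate":
        raise ValueError("run_bayes_cpi requires cfg.pi == 'estimate'")
    return _fit_design(_estimator_from_config(cfg, estimate_pi=True), design)


def run_bayes_c(design: GwasDesign, cfg: ChainConfig) -> PosteriorSamples:
    """Bayes-C with fixed pi (default protocol 41,000 / 1000 / thin 40)."""
    if isinstance(cfg.pi, str):
        raise ValueError("run_bayes_c requires a fixed numeric cfg.pi")
    return _fit_design(_estimator_from_config(cfg, estimate_pi=False), design)


def summarize_heritability(samples: PosteriorSamples) -> tuple[float, float]:
    """Posterior mean h2 over all saved states, and the SD of the last 100.

    Requires at least 100 saved states.
    """
    h2 = np.asarray(samples.h2, dtype=float)
    if len(h2) < 100:
        raise ValueError(f"need >= 100 saved samples, have {len(h2)}")
    return float(h2.mean()), float(np.std(h2[-100:], ddof=1))


def window_variance(
    samples: PosteriorSamples,
    marker_map: pd.DataFrame,
    threshold_report: float = 1.0,
    threshold_top: float = 3.0,
) -> pd.DataFrame:
    """Decompose genomic variance into non-overlapping 1-Mb windows.

    A marker at position ``bp`` on a chromosome belongs to window
    ``floor(bp / 1e6)``.  Per saved sample, the window's genomic value is
    Z_w u_w and its share is var over animals of that value divided by the
    variance of the total genomic value; samples with zero total genomic
    variance are skipped (counted and logged).  The reported percentage is
    100 x the posterior mean share.

    Returns a DataFrame with columns ``chromosome``, ``window_mb``, ``pct``,
    ``n_snps``, ``reported`` (pct > 1), ``top`` (pct > 3), sorted by
    chromosome and window.
    """
    if samples.Z is None:
        raise ValueError("samples must carry the centered dosage matrix Z")
    mm = marker_map.set_index("marker_id")
    idx_of = {mk: j for j, mk in enumerate(samples.marker_ids)}
    present = [mk for mk in samples.marker_ids if mk in mm.index]
    if not present:
        raise ValueError("no sampled markers found in the marker map")
    chrom = mm.loc[present, "chromosome"].to_numpy()
    wmb = (mm.loc[present, "position_bp"].to_numpy(dtype=np.int64) // 1_000_000)

    U = samples.effects                       # (S, m)
    Z = samples.Z
    n = Z.shape[0]
    G = Z @ U.T                               # (n, S) total genomic values
    vt = G.var(axis=0, ddof=1)
    valid = vt > 1e-300
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.info("skipped %d sample(s) with zero total genomic variance", n_skipped)

    rows = []
    key = pd.DataFrame({"chromosome": chrom, "window_mb": wmb, "marker": present})
    for (ch, w), grp in key.groupby(["chromosome", "window_mb"], sort=True):
        cols = [idx_of[mk] for mk in grp["marker"]]
        Gw = Z[:, cols] @ U[:, cols].T
        vw = Gw.var(axis=0, ddof=1)
        share = vw[valid] / vt[valid]
        pct = 100.0 * float(share.mean()) if valid.any() else 0.0
        rows.append({
            "chromosome": ch, "window_mb": int(w), "pct": pct, "n_snps": len(cols),
        })
    out = pd.DataFrame(rows).sort_values(["chromosome", "window_mb"]).reset_index(drop=True)
    out["reported"] = out["pct"] > threshold_report
    out["top"] = out["pct"] > threshold_top
    return out


def merge_adjacent(windows: pd.DataFrame, threshold: float = 3.0) -> pd.DataFrame:
    """Prune runs of adjacent above-threshold windows to their strongest member.

    Within each chromosome, maximal runs of consecutive 1-Mb windows whose
    percentages all exceed ``threshold`` are collapsed to the single window
    with the greatest percentage; windows at or below the threshold pass
    through unchanged.
    """
    keep = []
    for ch, grp in windows.groupby("chromosome", sort=False):
        grp = grp.sort_values("window_mb")
        run: list[int] = []
        prev_w = None
        for i, row in grp.iterrows():
            exceeds = row["pct"] > threshold
            adjacent = prev_w is not None and row["window_mb"] == prev_w + 1
            if exceeds and run and adjacent:
                run.append(i)
            else:
                if run:
                    keep.append(max(run, key=lambda j: windows.loc[j, "pct"]))
                run = [i] if exceeds else []
                if not exceeds:
                    keep.append(i)
            prev_w = row["window_mb"] if exceeds else None
        if run:
            keep.append(max(run, key=lambda j: windows.loc[j, "pct"]))
    return windows.loc[sorted(keep)].reset_index(drop=True)
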