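"""Tipping-point analysis of the between-arm correlation.

The free-correlation fit yields the *original* conclusions: for each
comparative measure (OR, RR, RD), whether its 95% CrI excludes the null,
and its point estimate.  The analysis then refits the model with rho fixed
at each point of a grid inside (-1, 1) and asks two questions per measure:

* interval tipping — at which grid values does the interval conclusion
  flip?  The tipping range T = [min, max] of those values is compared with
  the posterior of rho: a conclusion is judged "not robust" when T is
  nonempty and intersects the original 95% CrI of rho.
* magnitude tipping — at which grid values does the point estimate move by
  more than a threshold (default 15% and 30%) relative to the original?

The posterior mass of rho over the tipping region quantifies how plausible
the tipping values are under the original fit.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import MetaDataset
from .effects import COMPARATIVE, MEASURES, marginal_measures
from .model import BGLMM, _dataset_digest

__all__ = [
    "make_grid",
    "detect_interval_tipping",
    "relative_change",
    "detect_magnitude_tipping",
    "posterior_mass",
    "TippingAnalysis",
    "run_tipping",
]

RD_DEGENERACY_TOL = 1e-3   # |original RD| below this: relative change suppressed
GRID_CAP = 0.99            # keeps Sigma well-conditioned at the grid edges


def make_grid(rho_min: float = -1.0, rho_max: float = 1.0,
              step: float | None = 0.01, count: int | None = None) -> np.ndarray:
    """Equally spaced correlation values strictly inside (rho_min, rho_max).

    Step mode (default): values rho_min + b*step for b = 1, 2, ... while
    strictly below rho_max; the default (-1, 1) range with step 0.01 gives
    the 199 values -0.99, -0.98, ..., 0.99.  Count mode: ``count`` equally
    spaced interior points excluding both endpoints.  Values are capped at
    +/-0.99 so the random-effects covariance stays well-conditioned.
    """
    if not (-1 <= rho_min < rho_max <= 1):
        raise ValueError(f"invalid correlation range ({rho_min}, {rho_max})")
    if count is not None:
        if count < 2:
            raise ValueError("count mode needs at least 2 grid points")
        grid = rho_min + (rho_max - rho_min) * np.arange(1, count + 1) / (count + 1)
    else:
        if step is None or step <= 0:
            raise ValueError("step must be positive")
        if step >= rho_max - rho_min:
            raise ValueError("step must be smaller than the range width")
        n = int(np.floor((rho_max - rho_min) / step - 1e-9))
        grid = rho_min + step * np.arange(1, n + 1)
    grid = np.round(grid, 12)
    if np.any(np.abs(grid) > GRID_CAP + 1e-12):
        raise ValueError(f"grid values must lie within +/-{GRID_CAP}; "
                         "narrow the range or coarsen the step")
    return grid


def detect_interval_tipping(conclusions, original: bool, grid):
    """Tipping points where the interval conclusion differs from the original.

    Returns ``(tipping_set, tipping_range)`` with the range being the
    [min, max] envelope of the set — it may contain interior grid values
    whose conclusion did not flip when the conclusion oscillates — or
    ``None`` when no point flips.
    """
    conclusions = np.asarray(conclusions, dtype=bool)
    grid = np.asarray(grid, dtype=float)
    if conclusions.shape != grid.shape:
        raise ValueError("one conclusion per grid point is required")
    tips = grid[conclusions != bool(original)]
    if tips.size == 0:
        return tips, None
    return tips, (float(tips.min()), float(tips.max()))


def relative_change(new_estimate: float, original_estimate: float) -> float:
    """Signed relative change (new - original) / original."""
    if original_estimate == 0:
        raise ValueError("original estimate is 0; relative change is "
                         "undefined — use the absolute change instead")
    return (new_estimate - original_estimate) / original_estimate


def detect_magnitude_tipping(trajectory, grid, thresholds=(0.15, 0.30)):
    """Per-threshold tipping sets for the point-estimate trajectory.

    ``trajectory`` holds the relative change at each grid value; threshold
    t flags grid values with |relative change| > t.  Thresholds must be
    positive and strictly increasing.  Returns ``{t: (set, range_or_None)}``.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if trajectory.size == 0:
        raise ValueError("empty trajectory")
    if trajectory.shape != grid.shape:
        raise ValueError("trajectory and grid lengths differ")
    th = list(thresholds)
    if any(t <= 0 for t in th) or any(b <= a for a, b in zip(th, th[1:])):
        raise ValueError("thresholds must be positive and strictly increasing")
    out = {}
    for t in th:
        mask = np.abs(trajectory) > t
        tips = grid[mask]
        rng = (float(tips.min()), float(tips.max())) if tips.size else None
        out[t] = (tips, rng)
    return out


def posterior_mass(rho_draws, region, one_sided_at_boundary: bool = False,
                   grid_bounds=None):
    """Fraction of posterior rho draws falling in the closed ``region``.

    When the tipping set reaches the grid's upper (lower) end and
    ``one_sided_at_boundary`` is set, the region is extended to +1 (-1),
    so the mass reads Pr(rho >= min tipping point) (resp. <=).
    ``grid_bounds`` supplies the grid's (first, last) values for that check.
    """
    draws = np.asarray(rho_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty rho draws")
    if region is None:
        return 0.0
    lo, hi = float(region[0]), float(region[1])
    if lo < -1 or hi > 1:
        raise ValueError("region must lie within [-1, 1]")
    if one_sided_at_boundary and grid_bounds is not None:
        g_lo, g_hi = grid_bounds
        if np.isclose(hi, g_hi):
            hi = 1.0
        if np.isclose(lo, g_lo):
            lo = -1.0
    return float(np.mean((draws >= lo) & (draws <= hi)))


class TippingAnalysis(BaseEstimator):
    """Grid refits of the BGLMM with the between-arm correlation fixed.

    Parameters
    ----------
    rho_min, rho_max, step, count
        Grid specification, see :func:`make_grid`.  Defaults reproduce the
        199-point grid -0.99..0.99.
    thresholds : tuple of float
        Relative-change thresholds for magnitude tipping.
    chains, adaptation, iterations, burn_in, thin : int
        Per-grid-point MCMC schedule.  The default (2 chains x 20,000
        iterations, 5,000 burn-in, thinning 2) is deliberately lighter than
        the headline fit; pass the headline schedule for full replication.
    seed : int
        Base seed; each grid point gets a deterministic derived seed.

    Attributes
    ----------
    grid_ : ndarray
        The correlation grid.
    effects_ : pandas.DataFrame
        One row per (grid point, measure): median, CrI, flip flag,
        relative change, and the per-point convergence flag.
    tipping_sets_, tipping_ranges_ : dict
        Per comparative measure, the interval-tipping set and range.
    posterior_mass_ : dict
        Per measure, posterior mass of rho over the tipping region
        (one-sided when the tipping set reaches a grid boundary).
    magnitude_tipping_ : dict
        Per measure, ``{threshold: (set, range)}``.
    verdicts_ : dict
        Per measure, 'robust' or 'not robust' (not robust iff the tipping
        range is nonempty and intersects the original 95% CrI of rho).
    original_ : BGLMM
        The free-correlation fit the conclusions are compared against.
    """

    def __init__(self, rho_min=-1.0, rho_max=1.0, step=0.01, count=None,
                 thresholds=(0.15, 0.30), chains=2, adaptation=2_000,
                 iterations=20_000, burn_in=5_000, thin=2, seed=0):
        self.rho_min = rho_min
        self.rho_max = rho_max
        self.step = step
        self.count = count
        self.thresholds = thresholds
        self.chains = chains
        self.adaptation = adaptation
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed

    def fit(self, X, y=None, original: BGLMM | None = None):
        """Run the tipping analysis on dataset ``X``.

        ``original`` is the free-correlation, DIC-selected fit; when
        omitted it is computed here with the headline defaults
        (variance_structure='auto').
        """
        d = X if isinstance(X, MetaDataset) else MetaDataset.from_frame(X)
        if original is None:
            original = BGLMM(variance_structure="auto",
                             seed=int(self.seed)).fit(d)
        if original.rho_mode != "free":
            raise ValueError("the original fit must have a free correlation")
        if original.dataset_digest_ != _dataset_digest(d):
            raise ValueError("original fit was obtained on a different dataset")

        grid = make_grid(self.rho_min, self.rho_max, self.step, self.count)
        seeds = np.random.SeedSequence(int(self.seed)).spawn(len(grid))

        orig_summ = marginal_measures(original)
        rows = []
        converged = []
        for b, r in enumerate(grid):
            m = BGLMM(
                variance_structure=original.selected_structure_,
                rho_mode="fixed", rho_value=float(r),
                mu_sd=original.mu_sd, sigma_upper=original.sigma_upper,
                chains=self.chains, adaptation=self.adaptation,
                iterations=self.iterations, burn_in=self.burn_in,
                thin=self.thin,
                seed=int(seeds[b].generate_state(1)[0] % (2 ** 31)),
                keep_latent=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                m.fit(d)
            converged.append(m.converged_)
            for meas, s in marginal_measures(m).items():
                rows.append({"measure": meas, "rho": float(r),
                             "median": s.median, "lower": s.cri_lower,
                             "upper": s.cri_upper,
                             "excludes_null": s.excludes_null,
                             "converged": m.converged_})
        eff = pd.DataFrame(rows)

        self.dataset_ = d
        self.original_ = original
        self.original_summaries_ = orig_summ
        self.grid_ = grid
        self.converged_points_ = np.asarray(converged)
        if not self.converged_points_.all():
            bad = grid[~self.converged_points_]
            warnings.warn(f"{bad.size} grid-point fit(s) flagged as "
                          f"non-converged (rho = {np.round(bad, 3)})",
                          UserWarning)

        rho_med, rho_lo, rho_hi = original.summaries_.loc["rho"]
        self.rho_hat_ = float(rho_med)
        self.rho_cri_ = (float(rho_lo), float(rho_hi))

        self.tipping_sets_ = {}
        self.tipping_ranges_ = {}
        self.posterior_mass_ = {}
        self.magnitude_tipping_ = {}
        self.verdicts_ = {}
        flips = np.zeros(len(eff), dtype=bool)
        relchg = np.full(len(eff), np.nan)
        for meas in COMPARATIVE:
            sub = eff["measure"] == meas
            sub_idx = np.flatnonzero(sub.to_numpy())
            concl = eff.loc[sub, "excludes_null"].to_numpy(dtype=bool)
            orig_concl = bool(orig_summ[meas].excludes_null)
            tips, rng = detect_interval_tipping(concl, orig_concl, grid)
            self.tipping_sets_[meas] = tips
            self.tipping_ranges_[meas] = rng
            flips[sub_idx] = concl != orig_concl
            self.posterior_mass_[meas] = posterior_mass(
                original.draws_["rho"], rng, one_sided_at_boundary=True,
                grid_bounds=(grid[0], grid[-1])) if rng is not None else 0.0

            orig_med = orig_summ[meas].median
            meds = eff.loc[sub, "median"].to_numpy()
            if meas == "RD" and abs(orig_med) < RD_DEGENERACY_TOL:
                warnings.warn(
                    "original RD is within 1e-3 of 0; reporting absolute "
                    "instead of relative change for its trajectory",
                    UserWarning)
                traj = meds - orig_med
            else:
                traj = np.array([relative_change(m_, orig_med) for m_ in meds])
            relchg[sub_idx] = traj
            self.magnitude_tipping_[meas] = detect_magnitude_tipping(
                traj, grid, self.thresholds)

            not_robust = (rng is not None
                          and rng[0] <= self.rho_cri_[1]
                          and rng[1] >= self.rho_cri_[0])
            self.verdicts_[meas] = "not robust" if not_robust else "robust"

        eff["flipped"] = flips
        eff["relative_change"] = relchg
        self.effects_ = eff
        return self

    def rho_density(self, n_points: int = 201):
        """Kernel density of the original fit's rho draws on [-1, 1].

        Deterministic: draws are thinned to at most 20,000 before the KDE.
        """
        from scipy.stats import gaussian_kde
        draws = self.original_.draws_["rho"].to_numpy()
        if draws.size > 20_000:
            draws = draws[:: draws.size // 20_000 + 1]
        xs = np.linspace(-1.0, 1.0, n_points)
        if np.ptp(draws) < 1e-12:   # fixed-rho edge case
            ys = np.zeros_like(xs)
        else:
            ys = gaussian_kde(draws)(xs)
        return xs, ys

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "grid": self.grid_.tolist(),
            "rho_hat": self.rho_hat_,
            "rho_cri": list(self.rho_cri_),
            "original_summaries": {m: s.to_dict() for m, s in
                                   self.original_summaries_.items()},
            "tipping_sets": {m: v.tolist() for m, v in self.tipping_sets_.items()},
            "tipping_ranges": {m: (list(v) if v is not None else None)
                               for m, v in self.tipping_ranges_.items()},
            "posterior_mass": self.posterior_mass_,
            "magnitude_tipping": {
                m: {str(t): {"set": s.tolist(),
                             "range": list(r) if r is not None else None}
                    for t, (s, r) in d.items()}
                for m, d in self.magnitude_tipping_.items()},
            "verdicts": self.verdicts_,
            "effects": self.effects_.to_dict(orient="list"),
            "rho_density": [arr.tolist() for arr in self.rho_density()],
            "thresholds": list(self.thresholds),
            "params": self.get_params(),
        }
        return json.dumps(payload, indent=1)

    def to_csv(self, path_or_buf=None):
        """Tidy per-point table for external plotting."""
        cols = ["measure", "rho", "median", "lower", "upper", "flipped",
                "relative_change"]
        return self.effects_[cols].to_csv(path_or_buf, index=False)


def run_tipping(d: MetaDataset, original: BGLMM, **config) -> TippingAnalysis:
    """Functional wrapper over :class:`TippingAnalysis`."""
    return TippingAnalysis(**config).fit(d, original=original)
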