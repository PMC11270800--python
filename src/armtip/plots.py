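"""Robustness visualizations for the tipping-point analysis.

Two figures:

* the tipping plot — one panel per effect measure showing the point
  estimate and 95% CrI at every fixed value of the between-arm
  correlation, plus a panel with the posterior density of rho on the same
  axis.  Point colors encode robustness: black inside the original 95% CrI
  of rho, blue at its posterior median, red where the interval conclusion
  flipped, dark red where it flipped *inside* the CrI (the worrying case),
  and light gray outside the CrI without a flip.
* the trajectory plot — the relative change of each point estimate along
  the grid, red inside the rho CrI and black outside, with a blue dashed
  vertical line at the posterior median of rho and horizontal guides at
  the magnitude-tipping thresholds.

Figures are rendered with matplotlib; the underlying :class:`PlotSpec` is
JSON-serializable so a figure can be reproduced headlessly from a saved
analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["assign_color", "PlotSpec", "build_plot_spec", "tipping_plot",
           "trajectory_plot"]

COLORS = ("black", "blue", "red", "dark_red", "outside_gray")

_MPL_COLORS = {"black": "black", "blue": "tab:blue", "red": "red",
               "dark_red": "darkred", "outside_gray": "0.75"}

_PANEL_MEASURES = ("AR0", "AR1", "OR", "RR", "RD")


def assign_color(in_cri: bool, at_median: bool, flipped: bool) -> str:
    """Color for one grid point's effect estimate.

    A flip inside the rho CrI dominates everything (dark red); a flip
    outside is red; the posterior-median grid point is blue; unflipped
    points inside the CrI are black, and light gray outside it.
    """
    if flipped:
        return "dark_red" if in_cri else "red"
    if at_median:
        return "blue"
    if in_cri:
        return "black"
    return "outside_gray"


@dataclass
class PlotSpec:
    """Serializable description of the robustness figures."""

    panels: list          # per measure: rho, median, lower, upper, colors, null
    density_x: list
    density_y: list
    rho_hat: float
    rho_cri: tuple
    thresholds: tuple
    verdicts: dict
    posterior_mass: dict
    trajectories: dict = field(default_factory=dict)  # measure -> (rho, change, in_cri)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PlotSpec":
        payload = json.loads(text)
        payload["rho_cri"] = tuple(payload["rho_cri"])
        payload["thresholds"] = tuple(payload["thresholds"])
        return cls(**payload)

    def colors_present(self) -> set:
        out = set()
        for panel in self.panels:
            out.update(panel["colors"])
        return out


def _payload(analysis) -> dict:
    if isinstance(analysis, dict):
        return analysis
    return json.loads(analysis.to_json())


def build_plot_spec(analysis) -> PlotSpec:
    """Build the plot description from a fitted
    :class:`~armtip.tipping.TippingAnalysis` or its JSON payload.

    Pure function of the analysis results, so re-building from a
    serialized analysis gives an identical spec.
    """
    p = _payload(analysis)
    grid = np.asarray(p["grid"], dtype=float)
    rho_hat = float(p["rho_hat"])
    rho_lo, rho_hi = p["rho_cri"]
    in_cri = (grid >= rho_lo) & (grid <= rho_hi)
    at_median = np.zeros_like(in_cri)
    at_median[np.argmin(np.abs(grid - rho_hat))] = True

    eff = p["effects"]
    measure = np.asarray(eff["measure"])
    rho = np.asarray(eff["rho"], dtype=float)
    panels = []
    for meas in _PANEL_MEASURES:
        sel = measure == meas
        order = np.argsort(rho[sel])
        r = rho[sel][order]
        idx = np.searchsorted(grid, r)
        flipped = np.asarray(eff["flipped"])[sel][order].astype(bool)
        colors = [assign_color(bool(in_cri[i]), bool(at_median[i]), bool(f))
                  for i, f in zip(idx, flipped)]
        orig = p["original_summaries"][meas]
        panels.append({
            "measure": meas,
            "rho": r.tolist(),
            "median": np.asarray(eff["median"], dtype=float)[sel][order].tolist(),
            "lower": np.asarray(eff["lower"], dtype=float)[sel][order].tolist(),
            "upper": np.asarray(eff["upper"], dtype=float)[sel][order].tolist(),
            "colors": colors,
            "null_value": orig["null_value"],
        })

    trajectories = {}
    for meas in ("OR", "RR", "RD"):
        sel = measure == meas
        order = np.argsort(rho[sel])
        r = rho[sel][order]
        chg = np.asarray(eff["relative_change"], dtype=float)[sel][order]
        inside = ((r >= rho_lo) & (r <= rho_hi)).tolist()
        trajectories[meas] = {"rho": r.tolist(), "change": chg.tolist(),
                              "in_cri": inside}

    dx, dy = p["rho_density"]
    return PlotSpec(panels=panels, density_x=list(dx), density_y=list(dy),
                    rho_hat=rho_hat, rho_cri=(float(rho_lo), float(rho_hi)),
                    thresholds=tuple(p.get("thresholds", (0.15, 0.30))),
                    verdicts=dict(p["verdicts"]),
                    posterior_mass=dict(p["posterior_mass"]),
                    trajectories=trajectories)


def tipping_plot(analysis, path=None, figsize=(10, 12)):
    """Render the color-coded effect-vs-rho figure.

    Returns ``(spec, figure)``; saves to ``path`` when given (format from
    the extension: .png, .svg or .pdf).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.lines import Line2D

    spec = analysis if isinstance(analysis, PlotSpec) else build_plot_spec(analysis)
    n_panels = len(spec.panels) + 1
    fig, axes = plt.subplots(n_panels, 1, figsize=figsize, sharex=True)

    for ax, panel in zip(axes, spec.panels):
        r = np.asarray(panel["rho"])
        med = np.asarray(panel["median"])
        lo = np.asarray(panel["lower"])
        hi = np.asarray(panel["upper"])
        cols = [_MPL_COLORS[c] for c in panel["colors"]]
        for j in range(len(r)):
            ax.plot([r[j], r[j]], [lo[j], hi[j]], color=cols[j],
                    lw=0.8, alpha=0.7, zorder=1)
        ax.scatter(r, med, c=cols, s=8, zorder=2)
        if panel["null_value"] is not None:
            ax.axhline(panel["null_value"], color="0.4", ls=":", lw=1)
        ax.axvline(spec.rho_hat, color="tab:blue", ls="--", lw=1)
        ax.set_ylabel(panel["measure"])
        if panel["measure"] in spec.verdicts:
            mass = spec.posterior_mass.get(panel["measure"], 0.0)
            ax.set_title(
                f"{panel['measure']}: {spec.verdicts[panel['measure']]}"
                f" (tipping-region posterior mass {100 * mass:.1f}%)",
                fontsize=8, loc="right")

    axd = axes[-1]
    axd.fill_between(spec.density_x, spec.density_y, color="0.8")
    axd.plot(spec.density_x, spec.density_y, color="0.3", lw=1)
    axd.axvline(spec.rho_hat, color="tab:blue", ls="--", lw=1)
    for b in spec.rho_cri:
        axd.axvline(b, color="0.4", ls=":", lw=1)
    axd.set_ylabel("posterior\ndensity")
    axd.set_xlabel(r"between-arm correlation $\rho$")
    axd.set_xlim(-1, 1)

    present = sorted(spec.colors_present())
    handles = [Line2D([], [], marker="o", ls="", color=_MPL_COLORS[c], label=c)
               for c in present]
    axes[0].legend(handles=handles, fontsize=7, ncol=len(present),
                   loc="upper left")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return spec, fig


def trajectory_plot(analysis, path=None, figsize=(8, 8)):
    """Render the relative-change trajectory figure.

    Red segments mark grid values inside the original 95% CrI of rho,
    black outside; a blue dashed vertical line marks the posterior median
    of rho; horizontal guides sit at +/- each magnitude threshold.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    spec = analysis if isinstance(analysis, PlotSpec) else build_plot_spec(analysis)
    if not spec.trajectories:
        raise ValueError("no relative-change trajectories in this analysis")
    fig, axes = plt.subplots(len(spec.trajectories), 1, figsize=figsize,
                             sharex=True)
    axes = np.atleast_1d(axes)
    for ax, (meas, tr) in zip(axes, spec.trajectories.items()):
        r = np.asarray(tr["rho"])
        chg = np.asarray(tr["change"])
        inside = np.asarray(tr["in_cri"], dtype=bool)
        for j in range(len(r) - 1):
            color = "red" if inside[j] and inside[j + 1] else "black"
            ax.plot(r[j:j + 2], chg[j:j + 2], color=color, lw=1.2)
        for t in spec.thresholds:
            ax.axhline(t, color="0.5", ls=":", lw=0.8)
            ax.axhline(-t, color="0.5", ls=":", lw=0.8)
        ax.axvline(spec.rho_hat, color="tab:blue", ls="--", lw=1)
        ax.set_ylabel(f"relative change\n({meas})")
    axes[-1].set_xlabel(r"between-arm correlation $\rho$")
    axes[-1].set_xlim(-1, 1)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return spec, fig
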