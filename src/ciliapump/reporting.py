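"""Backing tables and plots for scenarios and figure presets.

Every emitted table carries the full parameter record (eps, alpha, beta,
hp and the driving condition) so each row is independently recomputable;
tables are plain pandas DataFrames written as RFC-4180 CSV with a fixed
column order, making repeated runs byte-identical.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .casson import axial_velocity
from .errors import ConfigurationError
from .flowfield import compute_field, trapping_metrics
from .params import CiliaParams, PumpState, gamma_factor
from .presets import FIGURE_PRESETS, figure_ids
from .pumping import (
    epsilon_crossing_flux,
    favorable_gradient_threshold,
    free_pumping_flux,
    mean_flow_rate,
    pressure_rise,
    pumping_integrals,
)

__all__ = [
    "figure_table",
    "render_figure",
    "thresholds_report",
    "scenario_table",
]

_COLS = ["figure", "kind", "eps", "alpha", "beta", "hp"]


def _params(base: dict, **over) -> CiliaParams:
    vals = dict(epsilon=0.25, alpha=0.4, beta=0.4, hp=0.0)
    vals.update(base)
    vals.update({k: v for k, v in over.items() if k in vals})
    return CiliaParams(**vals)


def _row(fig_id, kind, p: CiliaParams, **extra) -> dict:
    row = {"figure": fig_id, "kind": kind, "eps": p.epsilon, "alpha": p.alpha,
           "beta": p.beta, "hp": p.hp}
    row.update(extra)
    return row


def figure_table(fig_id: str, overrides: Optional[dict] = None) -> pd.DataFrame:
    """Backing table of one figure preset.

    ``overrides`` may replace the sweep list (key ``sweep_values``) or
    any base parameter; unprinted legend lists default to documented
    reconstructions (see :mod:`ciliapump.presets`).
    """
    if fig_id not in FIGURE_PRESETS:
        raise ConfigurationError(
            f"unknown figure id {fig_id!r}; valid ids: {', '.join(figure_ids())}"
        )
    spec = {k: v for k, v in FIGURE_PRESETS[fig_id].items()}
    overrides = dict(overrides or {})
    base = dict(spec["base"])
    base.update({k: overrides.pop(k) for k in list(overrides)
                 if k in ("epsilon", "alpha", "beta", "hp")})
    sweep_name, sweep_values = spec["sweep"]
    sweep_values = overrides.pop("sweep_values", sweep_values)
    kind = spec["kind"]
    rows: list[dict] = []

    if kind == "pump_curve":
        for val in sweep_values:
            p = _params(base, **{sweep_name: val})
            ints = pumping_integrals(p)
            for qb in spec["qbar"]:
                rows.append(_row(fig_id, kind, p, qbar=float(qb),
                                 delta_p=pressure_rise(float(qb), p, ints),
                                 i1=ints.i1, i2=ints.i2))
        cols = _COLS + ["qbar", "delta_p", "i1", "i2"]

    elif kind == "flow_vs_eps":
        for val in sweep_values:
            for eps in spec["eps"]:
                over = {sweep_name: val} if sweep_name != "delta_p" else {}
                p = _params(base, epsilon=float(eps), **over)
                dp = val if sweep_name == "delta_p" else spec["drive"]["delta_p"]
                rows.append(_row(fig_id, kind, p, delta_p=float(dp),
                                 qbar=mean_flow_rate(float(dp), p)))
        cols = _COLS + ["delta_p", "qbar"]

    elif kind == "flow_vs_param":
        pname, pgrid = spec["param"]
        dp = spec["drive"]["delta_p"]
        for val in sweep_values:
            for x in pgrid:
                p = _params(base, **{sweep_name: val, pname: float(x)})
                rows.append(_row(fig_id, kind, p, delta_p=float(dp),
                                 qbar=mean_flow_rate(float(dp), p)))
        cols = _COLS + ["delta_p", "qbar"]

    elif kind == "dpdz_profile":
        from .casson import pressure_gradient

        for val in sweep_values:
            over = {sweep_name: val} if sweep_name != "qbar" else {}
            p = _params(base, **over)
            qbar = val if sweep_name == "qbar" else spec["drive"]["qbar"]
            q = float(qbar) - gamma_factor(p.epsilon)
            for z in spec["z"]:
                rows.append(_row(fig_id, kind, p, qbar=float(qbar),
                                 z=float(z),
                                 dpdz=float(pressure_gradient(float(z), q, p))))
        cols = _COLS + ["qbar", "z", "dpdz"]

    elif kind == "velocity_profile":
        from .casson import pressure_gradient
        from .geometry import tube_radius

        z0 = float(spec["z"])
        for val in sweep_values:
            over = {sweep_name: val} if sweep_name != "qbar" else {}
            p = _params(base, **over)
            qbar = val if sweep_name == "qbar" else spec["drive"]["qbar"]
            q = float(qbar) - gamma_factor(p.epsilon)
            dpdz = float(pressure_gradient(z0, q, p))
            h0 = float(tube_radius(z0, p))
            for r in np.linspace(0.0, h0, 101):
                rows.append(_row(fig_id, kind, p, qbar=float(qbar), z=z0,
                                 r=float(r),
                                 w=float(axial_velocity(r, z0, dpdz, p))))
        cols = _COLS + ["qbar", "z", "r", "w"]

    elif kind == "streamlines":
        qbar = spec["drive"]["qbar"]
        for val in sweep_values:
            p = _params(base, **{sweep_name: val})
            ints = pumping_integrals(p)
            pump = PumpState.from_qbar(float(qbar), p, ints)
            tm = trapping_metrics(pump, p)
            rows.append(_row(fig_id, kind, p, qbar=float(qbar), q=pump.q,
                             n_boluses=tm.n_boluses,
                             bolus_area=tm.total_area))
        cols = _COLS + ["qbar", "q", "n_boluses", "bolus_area"]

    else:  # pragma: no cover - registry is closed
        raise ConfigurationError(f"unknown preset kind {kind!r}")

    return pd.DataFrame(rows, columns=cols)


def render_figure(fig_id: str, outdir, overrides: Optional[dict] = None):
    """Emit the backing CSV and a PNG plot for one figure preset.

    Returns the (csv_path, png_path) pair.  Plots are conveniences; all
    quantitative content lives in the CSV.
    """
    import pathlib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = figure_table(fig_id, overrides)
    csv_path = outdir / f"{fig_id}.csv"
    table.to_csv(csv_path, index=False, lineterminator="\n")

    kind = FIGURE_PRESETS[fig_id]["kind"]
    sweep_name, _ = FIGURE_PRESETS[fig_id]["sweep"]
    sweep_col = {"epsilon": "eps"}.get(sweep_name, sweep_name)
    fig, ax = plt.subplots(figsize=(5.5, 4.0))
    if kind == "pump_curve":
        for val, g in table.groupby(sweep_col):
            ax.plot(g["qbar"], g["delta_p"], label=f"{sweep_name}={val:g}")
        ax.set_xlabel("mean flow rate  Q̄")
        ax.set_ylabel("pressure rise  Δp")
    elif kind in ("flow_vs_eps",):
        xcol = "eps"
        for val, g in table.groupby(sweep_col if sweep_name != "delta_p"
                                    else "delta_p"):
            ax.plot(g[xcol], g["qbar"], label=f"{sweep_name}={val:g}")
        ax.set_xlabel("cilia length  ε")
        ax.set_ylabel("mean flow rate  Q̄")
    elif kind == "flow_vs_param":
        pname, _ = FIGURE_PRESETS[fig_id]["param"]
        xcol = {"epsilon": "eps"}.get(pname, pname)
        for val, g in table.groupby(sweep_col):
            ax.plot(g[xcol], g["qbar"], label=f"{sweep_name}={val:g}")
        ax.set_xlabel(pname)
        ax.set_ylabel("mean flow rate  Q̄")
    elif kind == "dpdz_profile":
        for val, g in table.groupby(sweep_col if sweep_name != "qbar"
                                    else "qbar"):
            ax.plot(g["z"], g["dpdz"], label=f"{sweep_name}={val:g}")
        ax.set_xlabel("z")
        ax.set_ylabel("dp/dz")
    elif kind == "velocity_profile":
        for val, g in table.groupby(sweep_col if sweep_name != "qbar"
                                    else "qbar"):
            ax.plot(g["r"], g["w"], label=f"{sweep_name}={val:g}")
        ax.set_xlabel("r")
        ax.set_ylabel("axial velocity  w")
    elif kind == "streamlines":
        plt.close(fig)
        png_path = outdir / f"{fig_id}.png"
        _render_streamline_panels(fig_id, table, png_path)
        return csv_path, png_path
    ax.legend(fontsize=8)
    ax.set_title(fig_id)
    fig.tight_layout()
    png_path = outdir / f"{fig_id}.png"
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return csv_path, png_path


def _render_streamline_panels(fig_id, table, png_path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = FIGURE_PRESETS[fig_id]
    sweep_name, sweep_values = spec["sweep"]
    qbar = spec["drive"]["qbar"]
    n = len(sweep_values)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.2), sharey=True)
    for ax, val in zip(np.atleast_1d(axes), sweep_values):
        p = _params(spec["base"], **{sweep_name: val})
        ints = pumping_integrals(p)
        pump = PumpState.from_qbar(float(qbar), p, ints)
        field = compute_field(pump, p, n_r=201, n_z=201)
        zz, rr = np.meshgrid(field.z_grid, field.r_grid, indexing="ij")
        levels = np.linspace(field.psi[field.mask].min(),
                             field.psi[field.mask].max(), 30)
        ax.contour(zz, rr, field.psi, levels=levels, linewidths=0.6)
        ax.plot(field.z_grid, 1 + p.epsilon * np.cos(2 * np.pi * field.z_grid),
                "k-", lw=1)
        ax.set_title(f"{sweep_name}={val:g}", fontsize=9)
        ax.set_xlabel("z")
    np.atleast_1d(axes)[0].set_ylabel("r")
    fig.suptitle(f"{fig_id}: wave-frame streamlines, Q̄={qbar:g}")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)


def thresholds_report(p: CiliaParams, eps_pair=None) -> dict:
    """Free-pumping flux, favorable-gradient threshold and (optionally)
    the epsilon-crossing flux for a parameter record."""
    ints = pumping_integrals(p)
    out = {
        "eps": p.epsilon, "alpha": p.alpha, "beta": p.beta, "hp": p.hp,
        "i1": ints.i1, "i2": ints.i2, "quadrature_points": ints.n_points,
        "est_error": ints.est_error,
        "free_pumping_flux": free_pumping_flux(p, ints),
        "favorable_gradient_threshold": favorable_gradient_threshold(p),
    }
    if eps_pair is not None:
        out["epsilon_pair"] = list(eps_pair)
        out["epsilon_crossing_flux"] = epsilon_crossing_flux(p, eps_pair)
    return out


def scenario_table(p: CiliaParams, qbar_values) -> pd.DataFrame:
    """Pump-curve table for an ad-hoc scenario (CSV-ready)."""
    from .pumping import pump_curve

    return pump_curve(p, qbar_values)
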