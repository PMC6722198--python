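"""Per-figure CSV and plot outputs for the scenario suite.

Time-series figures use a log concentration axis; spatial figures are heat
maps with a shared color scale per figure and darker shades for higher
concentrations. Each figure id writes ``figN.csv`` and ``figN.png``.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .experiments import (
    run_binding_scenarios,
    run_kinetics_sweep,
    run_permeability_sweep,
    run_spatial_maps,
)
from .model_core import Domain, default_params
from .pde_solver import default_output_times, simulate

__all__ = ["make_figures"]

_CMAP = "Greys"  # darker = higher


def _logplot(ax, t, series: dict, title: str):
    for label, y in series.items():
        ax.plot(t, np.maximum(y, 1e-12), label=label)
    ax.set_yscale("log")
    ax.set_xlabel("t (s)")
    ax.set_ylabel("concentration (µmol/L)")
    ax.set_title(title, fontsize=9)
    ax.legend(fontsize=6)


def _fig_binding(outdir: Path, dom: Domain | None, which: int) -> None:
    suite = run_binding_scenarios(dom=dom)
    t = suite.extras["times"]
    r0 = suite.results["no_binding"]
    rs = suite.results["specific_only"]
    rf = suite.results["full"]
    if which == 2:
        df = pd.DataFrame(
            {
                "t": t,
                "C_pl": r0.cpl,
                "C_no_binding": r0.center_C,
                "C_specific": rs.center_C,
                "B1_specific": rs.center_B1,
                "C_full": rf.center_C,
                "B1_full": rf.center_B1,
                "B2_full": rf.center_B2,
            }
        )
        fig, axes = plt.subplots(3, 2, figsize=(8, 9))
        _logplot(axes[0, 0], t, {"C_pl": r0.cpl, "C_ECF": r0.center_C}, "no binding")
        axes[0, 1].axis("off")
        _logplot(axes[1, 0], t, {"C_pl": rs.cpl, "C_ECF": rs.center_C}, "specific binding")
        _logplot(axes[1, 1], t, {"B1": rs.center_B1}, "specific binding")
        _logplot(axes[2, 0], t, {"C_pl": rf.cpl, "C_ECF": rf.center_C}, "specific + non-specific")
        _logplot(axes[2, 1], t, {"B1": rf.center_B1, "B2": rf.center_B2}, "specific + non-specific")
    else:  # 3: ratios
        df = pd.DataFrame(
            {
                "t": t,
                "ratio_C_specific_over_none": suite.extras["ratio_C_specific_over_none"],
                "ratio_C_full_over_none": suite.extras["ratio_C_full_over_none"],
                "ratio_B1_full_over_specific": suite.extras["ratio_B1_full_over_specific"],
            }
        )
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
        _logplot(
            axes[0],
            t,
            {
                "specific / none": df["ratio_C_specific_over_none"],
                "full / none": df["ratio_C_full_over_none"],
            },
            "C_ECF ratios",
        )
        _logplot(
            axes[1], t, {"B1 full / specific": df["ratio_B1_full_over_specific"]}, "B1 ratio"
        )
    _save(df, fig, outdir, which)


def _fig_kinetics(outdir: Path, dom: Domain | None, which: int) -> None:
    suite = run_kinetics_sweep(dom=dom)
    t = suite.extras["times"]
    attr = "center_C" if which == 4 else "center_B1"
    records = []
    fig, axes = plt.subplots(3, 3, figsize=(11, 9), sharex=True)
    for row, m_off in enumerate((0.1, 1.0, 10.0)):
        for col, m_on in enumerate((0.01, 1.0, 10.0)):
            ax = axes[row, col]
            series = {}
            for m_b in (0.01, 1.0, 100.0):
                y = getattr(suite.results[(m_on, m_off, m_b)], attr)
                series[f"B1max x{m_b:g}"] = y
                for tt, yy in zip(t, y):
                    records.append(
                        {"k1on_mult": m_on, "k1off_mult": m_off, "B1max_mult": m_b, "t": tt, attr: yy}
                    )
            _logplot(ax, t, series, f"k1on x{m_on:g}, k1off x{m_off:g}")
    _save(pd.DataFrame.from_records(records), fig, outdir, which)


def _fig_ratio100(outdir: Path, dom: Domain | None) -> None:
    dp, dos, dom0 = default_params()
    if dom is None:
        dom = dom0
    t = default_output_times(2e5, 300)
    base = simulate(dp, dos, dom, t_end=2e5, output_times=t)
    variants = {
        "B1max x100": dp.with_(B1max=dp.B1max * 100),
        "k1on x100": dp.with_(k1on=dp.k1on * 100),
        "k1off x0.1": dp.with_(k1off=dp.k1off * 0.1),
    }
    floor = 1e-12
    df = pd.DataFrame({"t": t})
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.5))
    for ax, attr in zip(axes, ("center_C", "center_B1", "center_B2")):
        series = {}
        for label, d in variants.items():
            r = simulate(d, dos, dom, t_end=2e5, output_times=t)
            ratio = getattr(r, attr) / np.maximum(getattr(base, attr), floor)
            series[label] = ratio
            df[f"{attr}_ratio_{label.replace(' ', '_')}"] = ratio
        _logplot(ax, t, series, f"{attr} ratio to default")
    _save(df, fig, outdir, 6)


def _fig_permeability(outdir: Path, dom: Domain | None) -> None:
    suite = run_permeability_sweep(dom=dom)
    t = suite.extras["times"]
    df = pd.DataFrame({"t": t, "C_pl": suite.results[1.0].cpl})
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.5))
    for ax, attr in zip(axes, ("center_C", "center_B1", "center_B2")):
        series = {"C_pl": suite.results[1.0].cpl}
        for m in (0.1, 1.0, 10.0):
            y = getattr(suite.results[m], attr)
            series[f"P x{m:g}"] = y
            df[f"{attr}_Px{m:g}"] = y
        _logplot(ax, t, series, attr)
    _save(df, fig, outdir, 7)


def _fig_spatial(outdir: Path, which: int, dom: Domain | None) -> None:
    suite = run_spatial_maps(dom=dom)
    result = suite.results["spatial"]
    attr = {8: "C", 9: "B1", 10: "B2"}[which]
    snaps = result.snapshots
    vmax = max(float(np.max(getattr(s, attr))) for s in snaps)
    rows = []
    fig, axes = plt.subplots(1, len(snaps), figsize=(4 * len(snaps), 3.6))
    g = result.grid
    for ax, snap in zip(np.atleast_1d(axes), snaps):
        arr = getattr(snap, attr)
        im = ax.imshow(
            arr.T,
            origin="lower",
            extent=(0, g.xr * 1e6, 0, g.yr * 1e6),
            cmap=_CMAP,
            vmin=0.0,
            vmax=vmax,
        )
        ax.set_title(f"{attr}, t = {snap.t:g} s", fontsize=9)
        ax.set_xlabel("x (µm)")
        ax.set_ylabel("y (µm)")
        fig.colorbar(im, ax=ax, shrink=0.8)
        ii, jj = np.meshgrid(np.arange(g.nx), np.arange(g.ny), indexing="ij")
        rows.append(
            pd.DataFrame(
                {
                    "t": snap.t,
                    "i": ii.ravel(),
                    "j": jj.ravel(),
                    "x_m": g.x[ii.ravel()],
                    "y_m": g.y[jj.ravel()],
                    attr: arr.ravel(),
                }
            )
        )
    _save(pd.concat(rows, ignore_index=True), fig, outdir, which)


def _save(df: pd.DataFrame, fig, outdir: Path, which: int) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / f"fig{which}.csv", index=False)
    fig.tight_layout()
    fig.savefig(outdir / f"fig{which}.png", dpi=120)
    plt.close(fig)


def make_figures(which: list[int], outdir: str | Path, dom: Domain | None = None) -> None:
    outdir = Path(outdir)
    for w in which:
        if w in (2, 3):
            _fig_binding(outdir, dom, w)
        elif w in (4, 5):
            _fig_kinetics(outdir, dom, w)
        elif w == 6:
            _fig_ratio100(outdir, dom)
        elif w == 7:
            _fig_permeability(outdir, dom)
        elif w in (8, 9, 10):
            _fig_spatial(outdir, w, dom)
        else:
            raise ValueError(f"unknown figure id {w}; valid ids are 2-10")
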