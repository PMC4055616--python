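"""Optional quick-look figures (scatter + fitted line).

Matplotlib is imported lazily so the core pipeline has no plotting
dependency; install the ``plots`` extra to use this module.  The figures are
working plots for sanity-checking a run, not publication graphics.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def save_figures(records, report, out_dir) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    written = []

    pairs = {
        "pp_vs_c": ("phyto_c_mgc_m3", "pp_mgc_m3_d",
                    "phytoplankton C (mgC m$^{-3}$)", "production (mgC m$^{-3}$ d$^{-1}$)"),
        "pp_vs_chl": ("chl_mg_m3", "pp_mgc_m3_d",
                      "chl a (mg m$^{-3}$)", "production (mgC m$^{-3}$ d$^{-1}$)"),
        "c_vs_chl": ("chl_mg_m3", "phyto_c_mgc_m3",
                     "chl a (mg m$^{-3}$)", "phytoplankton C (mgC m$^{-3}$)"),
    }
    for name, (xcol, ycol, xlab, ylab) in pairs.items():
        fit = report["fits"].get(name, {})
        fig, ax = plt.subplots(figsize=(4.5, 4))
        for region, g in records.groupby("region"):
            ax.scatter(np.log10(g[xcol]), np.log10(g[ycol]), s=14, label=region)
        if "slope" in fit:
            xs = np.linspace(
                np.log10(records[xcol].min()), np.log10(records[xcol].max()), 50
            )
            ax.plot(xs, fit["intercept"] + fit["slope"] * xs, "k-", lw=1)
            ax.set_title(f"RMA slope {fit['slope']:.2f}")
        ax.set_xlabel(f"log10 {xlab}")
        ax.set_ylabel(f"log10 {ylab}")
        ax.legend(fontsize=5)
        path = out_dir / f"fig_{name}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    for region, g in records.groupby("region"):
        ax.scatter(g["temp_c"], g["p_c"], s=14, label=region)
    tc = report.get("temp_correlation", {})
    if "r" in tc:
        ax.set_title(f"P$^C$ vs temperature, r = {tc['r']:.2f}")
    ax.set_xlabel("temperature (degC)")
    ax.set_ylabel("P$^C$ (d$^{-1}$)")
    ax.legend(fontsize=5)
    path = out_dir / "fig_pc_vs_temp.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    ok = records[np.isfinite(records["rsi"]) & ~records["rsi_excluded"]]
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for region, g in ok.groupby("region"):
        ax.scatter(g["rsi"], g["p_c"], s=14, label=region)
    rc = report.get("rsi_correlation", {})
    if "r" in rc:
        ax.set_title(f"P$^C$ vs RSI, r = {rc['r']:.2f}")
    ax.set_xlabel("RSI (mmol N kg$^{-1}$)")
    ax.set_ylabel("P$^C$ (d$^{-1}$)")
    ax.legend(fontsize=5)
    path = out_dir / "fig_pc_vs_rsi.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
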