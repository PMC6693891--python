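"""Matplotlib views of the magnetization and magnetocaloric tables."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_magnetization(curve: pd.DataFrame, kbt: float, path: str | Path) -> Path:
    """Moment and interaction energy vs field, one curve per cluster number,
    with the k_BT line on the energy panel."""
    fig, (ax_m, ax_e) = plt.subplots(1, 2, figsize=(10, 4))
    for n, grp in curve.groupby("n_clusters"):
        ax_m.semilogy(grp["b_tesla"], grp["moment_am2"].clip(lower=1e-30),
                      label=f"n = {n}")
        ax_e.semilogy(grp["b_tesla"], grp["energy_joule"].clip(lower=1e-30),
                      label=f"n = {n}")
    ax_e.axhline(kbt, ls="--", color="k", label=r"$k_BT$")
    ax_m.set_xlabel("B (T)")
    ax_m.set_ylabel(r"moment (A·m$^2$)")
    ax_e.set_xlabel("B (T)")
    ax_e.set_ylabel("interaction energy (J)")
    ax_e.legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_magnetocaloric(scan: pd.DataFrame, kbt: float, path: str | Path) -> Path:
    """Magneto-caloric energy transfer vs cluster number, one series per
    field value."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for b, grp in scan.groupby("b_tesla"):
        grp = grp.sort_values("n_clusters")
        ax.loglog(grp["n_clusters"], grp["energy_j"].clip(lower=1e-30),
                  "o-", label=f"B = {b:g} T")
    ax.axhline(kbt, ls="--", color="k", label=r"$k_BT$")
    ax.set_xlabel("cluster number n")
    ax.set_ylabel(r"$T\,|\Delta S|$ (J)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
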