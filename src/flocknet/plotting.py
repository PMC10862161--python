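"""Figure helpers: daily network snapshots and node-metric curves."""

from __future__ import annotations

import logging

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .socialnet import sri_network, to_networkx

log = logging.getLogger("flocknet")

__all__ = ["plot_network_snapshots", "plot_metric_curves"]


def _pick_snapshot_days(thi_daily) -> list[int]:
    """One day per distinct heat-stress category, lowest/median/highest THI."""
    order = np.argsort(thi_daily["thi"].to_numpy())
    picks = [order[0], order[len(order) // 2], order[-1]]
    return sorted(set(int(p) for p in picks))


def plot_network_snapshots(gbis, thi_daily, shade, grid, path):
    """Spring-layout snapshots with node size ∝ shade minutes and edge
    width ∝ SRI, for days spanning the observed THI range."""
    days = [d for d in _pick_snapshot_days(thi_daily) if d < len(gbis)]
    if not days:
        log.warning("no days to snapshot; figure skipped")
        return None
    fig, axes = plt.subplots(1, len(days), figsize=(5 * len(days), 5))
    if len(days) == 1:
        axes = [axes]
    shade = shade.copy()
    day_order = {d: k for k, d in enumerate(sorted(shade["day"].unique()))}
    shade["day_index"] = shade["day"].map(day_order)
    for ax, d in zip(axes, days):
        net = sri_network(gbis[d])
        g = to_networkx(net)
        sub = shade.loc[shade["day_index"] == d].set_index("id")["minutes"]
        sizes = [30 + 3 * float(sub.get(i, 0.0)) for i in g.nodes]
        pos = nx.spring_layout(g, seed=7, weight="weight")
        widths = [4 * g[u][v]["weight"] for u, v in g.edges]
        nx.draw_networkx_edges(g, pos, ax=ax, width=widths, alpha=0.4)
        nx.draw_networkx_nodes(g, pos, ax=ax, node_size=sizes,
                               node_color="tab:orange", edgecolors="k",
                               linewidths=0.5)
        thi = float(thi_daily["thi"].iloc[d])
        cat = str(thi_daily["category"].iloc[d])
        ax.set_title(f"day {d}: THI {thi:.2f} ({cat})")
        ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def plot_metric_curves(results, path):
    """Fitted quadratic of each node metric against scaled shade use."""
    fits = results.node_fits
    if not fits:
        log.warning("no node fits; figure skipped")
        return None
    z = np.linspace(-2.5, 2.5, 200)
    fig, axes = plt.subplots(1, len(fits), figsize=(4.5 * len(fits), 3.6))
    if len(fits) == 1:
        axes = [axes]
    for ax, (metric, fit) in zip(axes, fits.items()):
        eta = (
            fit.coef("intercept")
            + fit.coef("shade") * z
            + fit.coef("shade_sq") * z**2
        )
        y = np.exp(eta) if fit.family == "poisson" else eta
        ax.plot(z, y, lw=2)
        ax.set_xlabel("shade use (scaled)")
        ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
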