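"""Diagnostic figures: ACF with confidence bands, regime scatter,
recurrence plot, and per-session frequency bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .clustering import SIGN_LABELS

__all__ = ["plot_acf", "plot_regimes", "plot_recurrence", "plot_frequencies"]

REGIME_COLORS = {"+/+": "gold", "-/-": "black", "-/+": "tab:blue", "+/-": "tab:green"}


def plot_acf(acf_result, path=None, ax=None):
    """ACF curve, Bartlett band, and the cutoff-lag crossing point."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(acf_result.lags, acf_result.acf, lw=1.2, label="ACF")
    ax.fill_between(acf_result.lags, acf_result.ci_lower, acf_result.ci_upper,
                    alpha=0.3, label=f"Bartlett {1 - acf_result.alpha:.0%} band")
    if acf_result.t_cut is not None:
        u = np.interp(acf_result.t_cut, acf_result.lags, acf_result.ci_upper)
        ax.plot([acf_result.t_cut], [u], "ro", label=f"t_cut = {acf_result.t_cut:.0f} s")
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("autocorrelation")
    ax.legend()
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_regimes(results, path=None, ax=None):
    """Windows in the (Delta-E, Delta-HR) plane, colored by regime."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    df = results.window_features
    for lab in SIGN_LABELS:
        sel = df[df["regime"] == lab]
        ax.scatter(sel["delta_e"], sel["delta_hr"], s=6,
                   color=REGIME_COLORS[lab], label=lab)
    cent = results.centroids_unscaled()
    ax.scatter(cent["delta_e"], cent["delta_hr"], marker="x", c="red", s=60)
    ax.set_xlabel(r"$\Delta E$")
    ax.set_ylabel(r"$\Delta HR$")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.legend(title=f"mean silhouette {results.silhouette.mean:.2f}")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_recurrence(rqa_result, path=None, ax=None):
    """Binary recurrence raster (black = recurrent pair)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(rqa_result.matrix, cmap="Greys", origin="lower",
              interpolation="nearest")
    ax.set_xlabel("time index")
    ax.set_ylabel("time index")
    ax.set_title(f"RR = {rqa_result.rr:.3f}, DET = {rqa_result.det:.3f}")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_frequencies(per_session, path=None, ax=None):
    """Per-session regime frequency bars (cohort trend view)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(per_session))
    w = 0.2
    for i, lab in enumerate(SIGN_LABELS):
        ax.bar(x + (i - 1.5) * w, per_session[f"freq_{lab}"], width=w,
               color=REGIME_COLORS[lab], label=lab)
    ax.set_xticks(x)
    ax.set_xticklabels(per_session["session_id"], rotation=45, ha="right")
    ax.set_ylabel("regime frequency")
    ax.legend()
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
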