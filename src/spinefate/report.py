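"""Summary tables and figures for a processed spine-fate dataset."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import longitudinal, stats

__all__ = ["build_report"]


def _survival_table(spines: pd.DataFrame) -> pd.DataFrame:
    """Per-dendrite survival fractions by proximity, then treatment means."""
    rows = []
    for (treat, animal, sl, dend), grp in spines.groupby(
        ["treatment", "animal", "slice", "dendrite"]
    ):
        frac = longitudinal.survival_by_proximity(grp)
        rows.append({
            "treatment": treat, "animal": animal, "slice": sl, "dendrite": dend,
            "surv_proximal": frac["proximal"],
            "surv_non_proximal": frac["non_proximal"],
            "pct_loss": longitudinal.percent_spine_loss(grp["survived"]),
            "n_spines": len(grp),
        })
    return pd.DataFrame(rows)


def build_report(spines: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """Write per-group summary CSVs and figures; deterministic given input.

    Sections: event rates PRE/POST by treatment, ΔHz/Hz by treatment and
    spine fate, survival by proximity × treatment, and — when PsVue
    columns are present — ΔPsVue/PsVue by fate and proximity.  Returns a
    name → path map of everything written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    required = {"animal", "slice", "dendrite", "treatment", "survived",
                "proximity", "rate_pre", "rate_post"}
    missing = required - set(spines.columns)
    if missing:
        raise ValueError(f"spine table missing columns from upstream stages: {missing}")
    spines = longitudinal.annotate_changes(spines) \
        if "rel_change_hz" not in spines.columns else spines.copy()

    # --- rates PRE/POST ---------------------------------------------------
    long_rates = spines.melt(
        id_vars=["animal", "treatment"], value_vars=["rate_pre", "rate_post"],
        var_name="session", value_name="rate_hz",
    )
    rates = stats.animal_averages(long_rates, "rate_hz", ["treatment", "session"])
    p = out / "summary_rates.csv"
    rates.to_csv(p, index=False)
    written["rates"] = p

    # --- ΔHz/Hz by treatment × fate --------------------------------------
    rel = stats.animal_averages(
        spines, "rel_change_hz", ["treatment", "survived"]
    )
    p = out / "summary_rate_change.csv"
    rel.to_csv(p, index=False)
    written["rate_change"] = p

    # --- survival by proximity × treatment --------------------------------
    surv_dendrite = _survival_table(spines)
    surv = surv_dendrite.groupby("treatment", sort=True).agg(
        surv_proximal=("surv_proximal", "mean"),
        surv_non_proximal=("surv_non_proximal", "mean"),
        pct_loss=("pct_loss", "mean"),
        n_dendrites=("n_spines", "size"),
        n_spines=("n_spines", "sum"),
    ).reset_index()
    p = out / "summary_survival.csv"
    surv.to_csv(p, index=False)
    written["survival"] = p

    # --- PsVue ------------------------------------------------------------
    has_psvue = {"psvue_pre", "psvue_post"} <= set(spines.columns) \
        and spines["psvue_pre"].notna().any()
    if has_psvue:
        psv = stats.animal_averages(
            spines, "rel_change_psvue", ["treatment", "survived", "proximity"]
        )
        p = out / "summary_psvue.csv"
        psv.to_csv(p, index=False)
        written["psvue"] = p

    # --- figures ----------------------------------------------------------
    fig, ax = plt.subplots(figsize=(5, 4))
    for i, (treat, grp) in enumerate(rates.groupby("treatment")):
        grp = grp.set_index("session").loc[["rate_pre", "rate_post"]]
        ax.plot([i - 0.15, i + 0.15], grp["mean"], "o-", label=treat)
    ax.set_xticks(range(rates["treatment"].nunique()))
    ax.set_xticklabels(sorted(rates["treatment"].unique()), rotation=30)
    ax.set_ylabel("event rate (Hz), animal-averaged")
    ax.legend(fontsize=7)
    fig.tight_layout()
    p = out / "rates_pre_post.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written["fig_rates"] = p

    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.arange(len(surv))
    ax.bar(x - 0.2, surv["surv_proximal"], 0.4, label="astrocyte-proximal")
    ax.bar(x + 0.2, surv["surv_non_proximal"], 0.4, label="astrocyte-free")
    ax.set_xticks(x)
    ax.set_xticklabels(surv["treatment"], rotation=30)
    ax.set_ylabel("spine survival fraction (dendrite mean)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    p = out / "survival_by_proximity.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written["fig_survival"] = p

    if has_psvue:
        fig, ax = plt.subplots(figsize=(5, 4))
        psv_plot = psv.copy()
        psv_plot["label"] = (
            psv_plot["treatment"] + "/" +
            np.where(psv_plot["survived"], "kept", "lost") + "/" +
            np.where(psv_plot["proximity"], "astro+", "astro-")
        )
        ax.barh(psv_plot["label"], psv_plot["mean"])
        ax.set_xlabel("ΔPsVue/PsVue, animal-averaged")
        fig.tight_layout()
        p = out / "psvue_change.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["fig_psvue"] = p

    # dendrite-level table for reuse
    p = out / "dendrite_survival.csv"
    surv_dendrite.to_csv(p, index=False)
    written["dendrite_survival"] = p
    return written
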