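"""Drivers chaining simulator sweeps and statistics into the model's headline maps.

The computational experiment varies cell length (2L) and total MT number around
the wild-type-like operating point (2L = 14 um, 18 MTs) and scores each
condition by reliability delta, robustness sigma_x, and the failure coefficient
Phi.  The failure threshold x_f is derived from the wild-type-like condition:
its pooled (delta, sigma_x) parameterize a septum-offset surrogate whose
extreme-5% quantile defines x_f, after which Phi for every condition is the
Gaussian tail mass beyond x_f.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from mtpush.simulator import SimConfig, replicate_seed, sweep
from mtpush.stats import failure_coefficient, failure_threshold
from mtpush.synthetic import gen_septum_offsets

logger = logging.getLogger(__name__)

__all__ = ["pooled_summary", "phi_map", "phi_length_profile", "reproduce_fig7_maps"]

SCALES = {
    # (cell lengths 2L in um, total MT numbers, replicates per condition)
    "full": ([10.0, 12.0, 14.0, 16.0, 18.0, 20.0], [6, 10, 14, 18, 22, 26], 50),
    "desk": ([10.0, 12.0, 14.0, 16.0, 18.0, 20.0], [6, 10, 14, 18, 22], 20),
    "smoke": ([12.0, 14.0, 16.0], [6, 18], 2),
}
WT_LENGTH = 14.0
WT_N_MT = 18


def pooled_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Replicate-pooled delta and sigma_x per (length, n_mt) condition."""
    ok = df[df["ok"]] if "ok" in df else df
    agg = ok.groupby(["length", "n_mt"], as_index=False).agg(
        delta=("delta", "mean"),
        sigma_x=("sigma_x", "mean"),
        sigma_y=("sigma_y", "mean"),
        delta_sd=("delta", "std"),
        sigma_x_sd=("sigma_x", "std"),
        n_ok=("delta", "count"),
    )
    return agg


def derive_failure_threshold(
    pooled: pd.DataFrame,
    wt_length: float = WT_LENGTH,
    wt_n_mt: int = WT_N_MT,
    quantile: float = 0.05,
    placement_noise: float = 0.2,
    n_septa: int = 10_000,
    seed: int = 0,
) -> float:
    """x_f from the WT-like condition: extreme-(quantile) of a septum surrogate
    built from that condition's pooled delta and sigma_x."""
    row = pooled[(pooled["length"] == wt_length) & (pooled["n_mt"] == wt_n_mt)]
    if row.empty:
        raise ValueError(f"no ({wt_length} um, {wt_n_mt} MT) condition in the sweep")
    delta, sigma = float(row["delta"].iloc[0]), float(row["sigma_x"].iloc[0])
    offsets = gen_septum_offsets(
        delta, sigma, placement_noise=placement_noise, n=n_septa, seed=replicate_seed(seed, 0x5E)
    )
    return failure_threshold(offsets, quantile)


def phi_map(
    base: SimConfig,
    cell_lengths,
    mt_numbers,
    replicates: int,
    quantile: float = 0.05,
    placement_noise: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Sweep the (length, MT number) grid and attach condition-level Phi.

    Statistics follow the generation-time protocol: each cell starts with its
    nucleus at a tip and delta / sigma_x are taken over the whole 7200 s
    record, so the approach to center is part of the score (a real cell must
    center within one generation).  Returns (per-replicate frame, pooled frame
    with a ``phi`` column, x_f).
    """
    base = replace(base, burn_in=0.0)
    df = sweep(base, cell_lengths, mt_numbers, replicates)
    pooled = pooled_summary(df)
    xf = derive_failure_threshold(
        pooled, quantile=quantile, placement_noise=placement_noise, seed=base.seed
    )
    pooled["phi"] = [
        failure_coefficient(d, s, xf) for d, s in zip(pooled["delta"], pooled["sigma_x"])
    ]
    return df, pooled, xf


def phi_length_profile(
    base: SimConfig,
    cell_lengths=(10.0, 12.0, 14.0, 16.0, 18.0, 20.0),
    n_mt: int = WT_N_MT,
    replicates: int = 20,
    quantile: float = 0.05,
    placement_noise: float = 0.2,
) -> tuple[pd.DataFrame, float]:
    """Phi versus cell length at fixed MT number (one row of the Phi map)."""
    _, pooled, xf = phi_map(base, list(cell_lengths), [n_mt], replicates, quantile, placement_noise)
    return pooled.sort_values("length").reset_index(drop=True), xf


def _check_trends(pooled: pd.DataFrame) -> list[str]:
    """Qualitative structure the maps must show; returns failure messages."""
    problems = []
    at_wt_len = pooled[pooled["length"] == WT_LENGTH].sort_values("n_mt")
    if len(at_wt_len) >= 2 and not (
        at_wt_len["phi"].iloc[-1] <= at_wt_len["phi"].iloc[0]
    ):
        problems.append("Phi does not decrease with MT number at the WT-like length")
    at_wt_n = pooled[pooled["n_mt"] == WT_N_MT].sort_values("length")
    if len(at_wt_n) >= 3:
        phi = at_wt_n["phi"].to_numpy()
        lengths = at_wt_n["length"].to_numpy()
        beyond = phi[lengths > WT_LENGTH]
        if WT_LENGTH in lengths and beyond.size:
            if not beyond.max() > phi[lengths == WT_LENGTH][0]:
                problems.append("Phi does not increase beyond the WT-like cell length")
    return problems


def reproduce_fig7_maps(
    out_dir,
    scale: str = "desk",
    base: SimConfig | None = None,
    make_plots: bool = True,
) -> dict:
    """Run the (cell length x MT number) computational experiment and write the
    delta, sigma_x, and Phi grids (TSV) plus rendered maps.

    Raises RuntimeError if the qualitative structure of the maps (Phi falling
    with MT number, Phi minimal near the WT-like length) is absent.
    """
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {sorted(SCALES)}")
    lengths, numbers, reps = SCALES[scale]
    base = SimConfig() if base is None else base
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    df, pooled, xf = phi_map(base, lengths, numbers, reps)
    outputs = []
    per_rep_path = out_dir / "sweep_replicates.tsv"
    df.to_csv(per_rep_path, sep="\t", index=False, float_format="%.6g")
    outputs.append(per_rep_path)
    for col in ("delta", "sigma_x", "phi"):
        grid = pooled.pivot(index="n_mt", columns="length", values=col)
        p = out_dir / f"{col}_grid.tsv"
        grid.to_csv(p, sep="\t", float_format="%.6g")
        outputs.append(p)

    if make_plots:
        outputs += _render_maps(pooled, out_dir)

    from mtpush.io import write_manifest

    outputs.append(
        write_manifest(out_dir, seeds=[base.seed], outputs=outputs, cfg=base, extra={"xf_um": xf, "scale": scale})
    )
    problems = [] if scale == "smoke" else _check_trends(pooled)
    if problems:
        raise RuntimeError("map structure check failed: " + "; ".join(problems))
    return {"replicates": df, "pooled": pooled, "xf": xf, "outputs": outputs}


def _render_maps(pooled: pd.DataFrame, out_dir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    labels = {"delta": r"$\delta$ ($\mu$m)", "sigma_x": r"$\sigma_x$ ($\mu$m)", "phi": r"$\Phi$"}
    for col, label in labels.items():
        grid = pooled.pivot(index="n_mt", columns="length", values=col)
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.pcolormesh(grid.columns, grid.index, grid.to_numpy(), shading="nearest", cmap="viridis")
        fig.colorbar(im, ax=ax, label=label)
        ax.set_xlabel(r"cell length 2L ($\mu$m)")
        ax.set_ylabel("MT number")
        p = out_dir / f"{col}_map.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths
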