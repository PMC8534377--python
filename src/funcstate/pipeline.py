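"""Orchestration: full multiscale sweeps, corpus summaries and run manifests.

``sweep`` runs the complete per-network analysis — mean functional strength,
Von Neumann entropy and functional-module counts across one shared rescaled
tau grid — on a single spectral decomposition, and can persist the tables
with a manifest (config, seed, SHA-256 checksums) from which the run is
reproducible. ``corpus_summary`` repeats the sweep over a collection of
network files, applies the N <= max_nodes size filter, averages curves at
matched tau/tau_d ratios and pools the log-module-count vs entropy fit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DisconnectedError, ValidationError
from .networks import WeightedNetwork, read_network
from .diffusion import decompose, functional_state, rescaled_tau_grid
from .spectral_entropy import entropy_curve
from .functional_modules import (
    FitReport,
    functional_partition,
    modules_entropy_relation,
)

__all__ = ["SweepConfig", "SweepResult", "CorpusSummary", "sweep", "corpus_summary"]


@dataclasses.dataclass(frozen=True)
class SweepConfig:
    """Parameters of a multiscale sweep.

    Defaults follow the analysis conventions of this package: ratios
    tau/tau_d log-spaced in [1e-10, 10], phi0 = 1, networks capped at
    500 nodes (the full eigendecomposition is O(N^3)).
    """

    ratio_min: float = 1e-10
    ratio_max: float = 10.0
    n_points: int = 100
    phi0: float = 1.0
    seed: int = 0
    n_restarts: int = 10
    n_null: int = 20
    max_nodes: int = 500

    def __post_init__(self) -> None:
        if not (0 < self.ratio_min < self.ratio_max):
            raise ValidationError("ratio bounds must satisfy 0 < min < max")
        if self.n_points < 2:
            raise ValidationError("n_points must be >= 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class SweepResult:
    """Bundle of per-scale tables from one network sweep."""

    mean_strength_curve: pd.DataFrame
    entropy_curve: pd.DataFrame
    module_count_curve: pd.DataFrame
    partitions: pd.DataFrame
    manifest: dict

    def write(self, outdir: str | Path) -> dict:
        """Persist all tables as CSV plus a manifest.json with checksums."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "mean_strength_curve.csv": self.mean_strength_curve,
            "entropy_curve.csv": self.entropy_curve,
            "module_count_curve.csv": self.module_count_curve,
            "partitions.csv": self.partitions,
        }
        checksums = {}
        for name, df in tables.items():
            data = df.to_csv(index=False).encode()
            (outdir / name).write_bytes(data)
            checksums[name] = hashlib.sha256(data).hexdigest()
        manifest = dict(self.manifest, checksums=checksums)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest


def sweep(net: WeightedNetwork, config: SweepConfig | None = None) -> SweepResult:
    """Full multiscale analysis of one connected network.

    One spectral decomposition serves every scale. Outputs share the grid:
    the mean-strength curve rises from ~0 toward phi0*(N-1)/N, the entropy
    curve falls from log N toward 0, and the module-count curve moves from
    many small structure-like modules to few large ones.
    """
    if config is None:
        config = SweepConfig()
    if net.n_nodes > config.max_nodes:
        raise ValidationError(
            f"network has {net.n_nodes} nodes > max_nodes={config.max_nodes}; "
            "raise SweepConfig.max_nodes to analyze it anyway"
        )
    dec = decompose(net)
    if not dec.is_connected:
        raise DisconnectedError("diffusion time undefined (lambda_2 = 0)")
    grid = rescaled_tau_grid(dec, config.ratio_min, config.ratio_max, config.n_points)

    strength_rows = []
    module_rows = []
    part_rows = []
    for ratio, tau in grid:
        state = functional_state(dec, tau, phi0=config.phi0)
        strength_rows.append((ratio, tau, state.mean_strength, state.mean_strength / config.phi0))
        part = functional_partition(
            net, tau, phi0=config.phi0, seed=config.seed,
            n_restarts=config.n_restarts, dec=dec,
        )
        module_rows.append((ratio, tau, part.n_modules, part.modularity))
        for label, module in zip(net.node_labels, part.assignment):
            part_rows.append((ratio, label, int(module)))

    strength_df = pd.DataFrame(
        strength_rows,
        columns=["tau_over_taud", "tau", "mean_strength", "mean_strength_over_phi0"],
    )
    modules_df = pd.DataFrame(
        module_rows, columns=["tau_over_taud", "tau", "n_modules", "modularity"]
    )
    parts_df = pd.DataFrame(part_rows, columns=["tau_over_taud", "node", "module"])
    entropy_df = entropy_curve(net, grid, dec=dec)

    manifest = {
        "config": config.to_dict(),
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "diffusion_time": dec.diffusion_time,
    }
    return SweepResult(strength_df, entropy_df, modules_df, parts_df, manifest)


@dataclasses.dataclass(frozen=True)
class CorpusSummary:
    """Cross-network averages at matched rescaled scales."""

    entropy_summary: pd.DataFrame
    module_summary: pd.DataFrame
    strength_summary: pd.DataFrame
    pooled_fit: FitReport
    n_analyzed: int
    rejections: dict[str, str]


def corpus_summary(
    networks: list[WeightedNetwork] | list[str] | list[Path],
    config: SweepConfig | None = None,
) -> CorpusSummary:
    """Sweep a corpus and average curves across networks.

    Accepts in-memory networks or edge-list file paths. Networks larger than
    ``max_nodes`` or disconnected ones are rejected with a per-item reason;
    survivors are swept and their curves averaged at matched tau/tau_d
    ratios (each network evaluated at its own tau = r * tau_d, no
    interpolation). The modules–entropy relation is fit on points pooled
    over all networks and scales.
    """
    if config is None:
        config = SweepConfig()
    rejections: dict[str, str] = {}
    results: list[SweepResult] = []
    for item in networks:
        if isinstance(item, (str, Path)):
            name = str(item)
            try:
                net = read_network(item)
            except Exception as exc:
                rejections[name] = f"unreadable: {exc}"
                continue
        else:
            name, net = f"network_{len(results) + len(rejections)}", item
        try:
            results.append(sweep(net, config))
        except (ValidationError, DisconnectedError) as exc:
            rejections[name] = str(exc)
    if not results:
        detail = "; ".join(f"{k}: {v}" for k, v in rejections.items()) or "empty corpus"
        raise ValidationError(f"no network survived the filters ({detail})")

    def _summarize(frames: list[pd.DataFrame], col: str) -> pd.DataFrame:
        stacked = pd.concat(frames).groupby("tau_over_taud")[col]
        out = stacked.agg(["mean", "std", "count"]).reset_index()
        return out.rename(columns={"mean": f"{col}_mean", "std": f"{col}_sd", "count": "n"})

    entropy_sum = _summarize([r.entropy_curve for r in results], "entropy")
    module_sum = _summarize([r.module_count_curve for r in results], "n_modules")
    strength_sum = _summarize([r.mean_strength_curve for r in results], "mean_strength")

    pooled_m = np.concatenate([r.module_count_curve["n_modules"].to_numpy() for r in results])
    pooled_s = np.concatenate([r.entropy_curve["entropy"].to_numpy() for r in results])
    fit = modules_entropy_relation(pooled_m, pooled_s)

    return CorpusSummary(
        entropy_summary=entropy_sum,
        module_summary=module_sum,
        strength_summary=strength_sum,
        pooled_fit=fit,
        n_analyzed=len(results),
        rejections=rejections,
    )
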