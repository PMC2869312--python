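"""Configuration files, trajectory serialization, and run manifests.

Config files are YAML with a flat ``key: value`` layout mirroring
:class:`~psdcrowd.lattice.SimulationConfig` plus an optional ``field``
block (C, P, arrangement, region, energy).  Trajectories round-trip either
through a compact binary ``.npz`` table (default) or a plain-text ``.tsv``
with one row per (walker, record).  All headers state units: ms, µm, k_BT.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import EnsembleResult, Trajectory
from .lattice import (
    DEFAULT_D_FREE,
    DEFAULT_DT,
    DEFAULT_RECORD_INTERVAL,
    ObstacleField,
    PSDRegion,
    SimulationConfig,
    ValidationError,
    assign_binding,
    make_config,
    make_obstacle_field,
)

__all__ = [
    "RunManifest",
    "load_config",
    "save_config",
    "build_field",
    "write_trajectories",
    "read_trajectories",
    "write_field_sites",
    "read_field_sites",
]

_CONFIG_KEYS = {
    "width",
    "height",
    "duration",
    "n_walkers",
    "dt",
    "D_free",
    "record_interval",
    "seed",
}
_FIELD_KEYS = {"C", "P", "arrangement", "region", "energy"}
_CONFIG_DEFAULTS = {
    "dt": DEFAULT_DT,
    "D_free": DEFAULT_D_FREE,
    "record_interval": DEFAULT_RECORD_INTERVAL,
    "n_walkers": 400,
    "seed": 0,
}

SEED_RULE = (
    "per-walker seeds = SeedSequence(master).generate_state(n) & 0x7fffffff; "
    "start sites from default_rng(SeedSequence([master, 1]))"
)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-exactly."""

    config: dict
    master_seed: int
    seed_rule: str
    field_digest: str
    version: str
    timestamp: str

    @classmethod
    def for_run(cls, config: SimulationConfig, field_digest: str) -> "RunManifest":
        from . import __version__

        return cls(
            config=asdict(config),
            master_seed=config.seed,
            seed_rule=SEED_RULE,
            field_digest=field_digest,
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def load_config(path) -> tuple[SimulationConfig, dict]:
    """Load and validate a YAML run configuration.

    Returns the simulation config (defaults applied) and the ``field``
    parameter block as a plain dict (empty when absent).  Unknown keys are
    rejected by name.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError("config: file does not contain a key/value mapping")
    unknown = set(raw) - _CONFIG_KEYS - {"field"}
    if unknown:
        raise ValidationError(f"config: unknown key(s) {sorted(unknown)}")
    missing = {"width", "height", "duration"} - set(raw)
    if missing:
        raise ValidationError(f"config: missing required key(s) {sorted(missing)}")
    kwargs = dict(_CONFIG_DEFAULTS)
    kwargs.update({k: raw[k] for k in raw if k in _CONFIG_KEYS})
    config = make_config(**kwargs)
    field_block = raw.get("field") or {}
    if not isinstance(field_block, dict):
        raise ValidationError("field: must be a mapping")
    unknown = set(field_block) - _FIELD_KEYS
    if unknown:
        raise ValidationError(f"field: unknown key(s) {sorted(unknown)}")
    return config, field_block


def save_config(path, config: SimulationConfig, field_block: dict | None = None) -> None:
    doc = asdict(config)
    if field_block:
        doc["field"] = field_block
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def build_field(config: SimulationConfig, field_block: dict) -> ObstacleField:
    """Realize the ``field`` block of a config file as an ObstacleField."""
    region = field_block.get("region")
    if region is not None:
        region = PSDRegion(*[float(v) for v in region])
    fld = make_obstacle_field(
        config,
        C=float(field_block.get("C", 0.0)),
        region=region,
        arrangement=field_block.get("arrangement", "random"),
        seed=field_block.get("seed", config.seed),
    )
    P = float(field_block.get("P", 0.0))
    if P > 0:
        energy = field_block.get("energy", 0.0)
        if isinstance(energy, dict):
            if energy.get("kind") == "uniform":
                spec = ("uniform", float(energy["lo"]), float(energy["hi"]))
            else:
                spec = float(energy.get("value", 0.0))
        else:
            spec = float(energy)
        fld = assign_binding(fld, P=P, energy_spec=spec, seed=config.seed)
    return fld


# ---------------------------------------------------------------------------
# Trajectory tables


def _ensemble_frame(ensemble: EnsembleResult) -> pd.DataFrame:
    rows = []
    for w, tr in enumerate(ensemble.trajectories):
        rows.append(
            pd.DataFrame(
                {
                    "walker_id": w,
                    "t_ms": tr.times,
                    "x_um": tr.positions_unwrapped[:, 0],
                    "y_um": tr.positions_unwrapped[:, 1],
                    "i": tr.positions_wrapped[:, 0],
                    "j": tr.positions_wrapped[:, 1],
                    "bound": tr.bound_flags.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_trajectories(ensemble: EnsembleResult, path) -> None:
    """Serialize an ensemble: ``.npz`` binary table or plain-text ``.tsv``.

    Both formats carry the run manifest; the round-trip is lossless for
    times, wrapped and unwrapped positions, and bound flags.
    """
    path = Path(path)
    manifest = RunManifest.for_run(ensemble.config, ensemble.field_digest)
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            times=ensemble.times,
            unwrapped=ensemble.unwrapped(),
            wrapped=ensemble.wrapped(),
            bound=np.stack([t.bound_flags for t in ensemble.trajectories]),
            manifest=np.array(manifest.to_json()),
        )
    else:
        frame = _ensemble_frame(ensemble)
        with open(path, "w") as fh:
            fh.write("# psdcrowd trajectories (units: ms, um; wrapped i,j are lattice sites)\n")
            fh.write(f"# manifest: {manifest.to_json()}\n")
            frame.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_trajectories(path) -> EnsembleResult:
    """Load an ensemble written by :func:`write_trajectories`."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as data:
            manifest = json.loads(str(data["manifest"]))
            config = make_config(**manifest["config"])
            times = data["times"]
            unwrapped, wrapped, bound = data["unwrapped"], data["wrapped"], data["bound"]
            trajectories = [
                Trajectory(times, unwrapped[w], wrapped[w], bound[w])
                for w in range(unwrapped.shape[0])
            ]
            return EnsembleResult(
                config=config,
                trajectories=trajectories,
                seed=manifest["master_seed"],
                field_digest=manifest["field_digest"],
            )
    manifest = None
    with open(path) as fh:
        header = []
        for line in fh:
            if not line.startswith("#"):
                header.append(line)
                break
            if line.startswith("# manifest:"):
                manifest = json.loads(line.split(":", 1)[1])
        body = "".join(header) + fh.read()
    if manifest is None:
        raise ValidationError(f"{path}: missing manifest header line")
    from io import StringIO

    try:
        frame = pd.read_csv(StringIO(body), sep="\t", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surfaced with file context
        raise ValidationError(f"{path}: malformed trajectory table: {exc}") from exc
    expected = {"walker_id", "t_ms", "x_um", "y_um", "i", "j", "bound"}
    if set(frame.columns) != expected:
        raise ValidationError(f"{path}: expected columns {sorted(expected)}")
    config = make_config(**manifest["config"])
    trajectories = []
    n_times = None
    for w, grp in frame.groupby("walker_id", sort=True):
        if n_times is None:
            n_times = len(grp)
        elif len(grp) != n_times:
            raise ValidationError(
                f"{path}: walker {w} has {len(grp)} records, expected {n_times} "
                f"(file truncated?) near line {grp.index[-1] + 4}"
            )
        trajectories.append(
            Trajectory(
                times=grp["t_ms"].to_numpy(),
                positions_unwrapped=grp[["x_um", "y_um"]].to_numpy(),
                positions_wrapped=grp[["i", "j"]].to_numpy(dtype=np.int64),
                bound_flags=grp["bound"].to_numpy(dtype=bool),
            )
        )
    if (config.n_records + 1) != n_times:
        raise ValidationError(
            f"{path}: {n_times} records per walker but config implies {config.n_records + 1} "
            "(file truncated?)"
        )
    return EnsembleResult(
        config=config,
        trajectories=trajectories,
        seed=manifest["master_seed"],
        field_digest=manifest["field_digest"],
    )


def write_field_sites(field: ObstacleField, path) -> None:
    """Plain-text occupied-site list (columns: i, j, bindable, energy_kbt)."""
    table = field.site_table()
    with open(path, "w") as fh:
        fh.write("# psdcrowd obstacle field (energy in kBT)\n")
        fh.write(f"# C_target: {field.C_target}  P_target: {field.P_target}  arrangement: {field.arrangement}\n")
        fh.write(f"# grid: {field.config.nx} {field.config.ny}\n")
        fh.write("i\tj\tbindable\tenergy_kbt\n")
        for row in table:
            fh.write(f"{int(row[0])}\t{int(row[1])}\t{int(row[2])}\t{row[3]:.17g}\n")


def read_field_sites(path, config: SimulationConfig) -> ObstacleField:
    """Rebuild an ObstacleField from a site list written by write_field_sites."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    occupied = np.zeros((config.nx, config.ny), dtype=bool)
    bindable = np.zeros_like(occupied)
    energy = np.zeros(occupied.shape, dtype=np.float64)
    ii = frame["i"].to_numpy(dtype=int)
    jj = frame["j"].to_numpy(dtype=int)
    occupied[ii, jj] = True
    bmask = frame["bindable"].to_numpy(dtype=bool)
    bindable[ii[bmask], jj[bmask]] = True
    energy[ii[bmask], jj[bmask]] = frame["energy_kbt"].to_numpy()[bmask]
    n_occ = occupied.sum()
    return ObstacleField(
        config=config,
        occupied=occupied,
        bindable=bindable,
        energy=energy,
        C_target=float(n_occ / occupied.size),
        P_target=float(bindable.sum() / n_occ) if n_occ else 0.0,
        arrangement="random",
    )
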