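"""Synthetic datasets with the statistical structure of the experiment.

A dataset is a set of replicate trajectories over named treatments:
per-replicate random arena layouts (for random/non-binary treatments), a
fair-coin HQ-side assignment, trajectories simulated from a generating
policy, and an optional exclusion flag emulating replicates discarded from
analysis (cells that left the arm). Excluded replicates are kept in the
files with a flag — analysis stages skip them — so exclusion handling is
itself testable. Everything is reproducible from the dataset seed, and the
manifest records every derived seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arena import TREATMENT_NAMES, Treatment, make_treatment
from .decision_models import PolicySpec
from .simulator import Move, Trajectory, simulate_trajectory

_CSV_COLUMNS = ("replicate_id", "treatment", "hq_side", "step", "arm", "site", "reward")


class TrajectoryFormatError(ValueError):
    """A trajectory file violates the CSV contract; the message names the row."""


@dataclass(frozen=True)
class DatasetSpec:
    """Recipe for one synthetic dataset."""

    treatments: tuple[str, ...]
    n_replicates: int  # per treatment
    model: PolicySpec
    seed: int
    exclusion_rate: float = 0.0
    graded: bool = True

    def __post_init__(self) -> None:
        if not self.treatments:
            raise ValueError("at least one treatment is required")
        unknown = set(self.treatments) - set(TREATMENT_NAMES)
        if unknown:
            raise KeyError(f"unknown treatments: {sorted(unknown)}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.exclusion_rate < 1.0:
            raise ValueError("exclusion_rate must be in [0, 1)")


def generate_dataset(spec: DatasetSpec) -> tuple[list[Trajectory], dict]:
    """Simulate a dataset; returns (trajectories, manifest).

    Per replicate: a fresh layout seed (used by random/non-binary
    treatments), a fair-coin HQ side, a trajectory seed, and an exclusion
    draw — all taken from one master stream so the dataset is bitwise
    reproducible from ``spec.seed``.
    """
    master = np.random.default_rng(spec.seed)
    trajectories: list[Trajectory] = []
    replicates = []
    rep_id = 0
    for name in spec.treatments:
        for _ in range(spec.n_replicates):
            layout_seed = int(master.integers(2**31))
            hq_side = "left" if master.random() < 0.5 else "right"
            traj_seed = int(master.integers(2**31))
            excluded = bool(master.random() < spec.exclusion_rate)
            treatment = make_treatment(name, seed=layout_seed, hq_side=hq_side)
            traj = simulate_trajectory(spec.model, treatment, traj_seed, graded=spec.graded)
            traj.excluded = excluded
            trajectories.append(traj)
            replicates.append(
                {
                    "replicate_id": rep_id,
                    "treatment": name,
                    "layout_seed": layout_seed,
                    "hq_side": hq_side,
                    "traj_seed": traj_seed,
                    "excluded": excluded,
                }
            )
            rep_id += 1
    manifest = {
        "seed": spec.seed,
        "treatments": list(spec.treatments),
        "n_replicates": spec.n_replicates,
        "model": {
            "model_id": spec.model.model_id,
            "theta": spec.model.theta,
            "gittins_discount": spec.model.gittins_discount,
        },
        "exclusion_rate": spec.exclusion_rate,
        "graded": spec.graded,
        "replicates": replicates,
    }
    return trajectories, manifest


def rebuild_treatments(manifest: dict) -> dict[int, Treatment]:
    """Reconstruct each replicate's arena from the manifest seeds."""
    return {
        r["replicate_id"]: make_treatment(
            r["treatment"], seed=r["layout_seed"], hq_side=r["hq_side"]
        )
        for r in manifest["replicates"]
    }


# --- file I/O ---------------------------------------------------------------


def write_trajectories(trajectories: list[Trajectory], path: str | Path) -> None:
    """One move per row; UTF-8 CSV with a mandatory header."""
    rows = []
    for rep_id, t in enumerate(trajectories):
        for m in t.moves:
            rows.append(
                {
                    "replicate_id": rep_id,
                    "treatment": t.treatment_name,
                    "hq_side": t.hq_side,
                    "step": m.step,
                    "arm": m.arm,
                    "site": m.site,
                    "reward": m.reward,
                    "excluded": t.excluded,
                    "seed": t.seed if t.seed is not None else -1,
                }
            )
    frame = pd.DataFrame(rows, columns=list(_CSV_COLUMNS) + ["excluded", "seed"])
    frame.to_csv(path, index=False, encoding="utf-8")


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))


def read_manifest(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def read_trajectories(
    path: str | Path,
    treatments: dict[int, Treatment] | None = None,
) -> list[Trajectory]:
    """Parse a trajectory CSV, validating structure row by row.

    ``treatments`` (replicate_id -> Treatment, e.g. from
    :func:`rebuild_treatments`) re-attaches arenas so chemotaxis/likelihood
    replay is possible; without it trajectories carry ``treatment=None``.
    Malformed rows raise :class:`TrajectoryFormatError` naming the CSV row.
    """
    frame = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise TrajectoryFormatError(f"missing columns: {sorted(missing)}")
    if frame.empty:
        return []
    trajectories: list[Trajectory] = []
    for rep_id, group in frame.groupby("replicate_id", sort=False):
        group = group.sort_values("step")
        hq_sides = group["hq_side"].unique()
        names = group["treatment"].unique()
        if len(hq_sides) != 1 or len(names) != 1:
            row = int(group.index[0]) + 2
            raise TrajectoryFormatError(
                f"row {row}: replicate {rep_id} mixes treatments or hq_side values"
            )
        hq_side = str(hq_sides[0])
        if hq_side not in ("left", "right"):
            row = int(group.index[0]) + 2
            raise TrajectoryFormatError(f"row {row}: unknown hq_side {hq_side!r}")
        pos = {"left": 1, "right": 1}
        moves: list[Move] = []
        for idx, rec in group.iterrows():
            row = int(idx) + 2  # 1-based, plus header
            arm = str(rec["arm"])
            if arm not in ("left", "right"):
                raise TrajectoryFormatError(f"row {row}: unknown arm label {arm!r}")
            site = int(rec["site"])
            if site != pos[arm] + 1:
                raise TrajectoryFormatError(
                    f"row {row}: site {site} on {arm} arm breaks the sequence "
                    f"(expected {pos[arm] + 1})"
                )
            pos[arm] = site
            moves.append(Move(int(rec["step"]), arm, site, float(rec["reward"])))
        last_arm = moves[-1].arm
        end_cause = "hq_end_first" if last_arm == hq_side else "lq_end_first"
        excluded = bool(group["excluded"].iloc[0]) if "excluded" in group else False
        seed = int(group["seed"].iloc[0]) if "seed" in group else -1
        treatment = treatments.get(int(rep_id)) if treatments else None
        if treatment is not None:
            treatment = treatment.with_hq_side(hq_side)
        trajectories.append(
            Trajectory(
                treatment_name=str(names[0]),
                hq_side=hq_side,
                moves=moves,
                end_cause=end_cause,
                seed=None if seed == -1 else seed,
                excluded=excluded,
                treatment=treatment,
            )
        )
    return trajectories


def write_dataset(
    trajectories: list[Trajectory], manifest: dict, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write trajectories.csv + manifest.yaml into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "trajectories.csv"
    manifest_path = out / "manifest.yaml"
    write_trajectories(trajectories, csv_path)
    write_manifest(manifest, manifest_path)
    return csv_path, manifest_path


def load_dataset(data_dir: str | Path) -> list[Trajectory]:
    """Read a dataset directory written by :func:`write_dataset`, arenas attached."""
    data = Path(data_dir)
    manifest = read_manifest(data / "manifest.yaml")
    return read_trajectories(data / "trajectories.csv", rebuild_treatments(manifest))
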