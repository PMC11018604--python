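"""Session-bundle I/O (plain-text CSV + YAML).

A session directory holds: config.yaml, trajectory.csv (frame, t, x, y,
hd), activity.csv (cells x frames), bouts.csv (object_id, lap,
frame_start, frame_end, label), ground_truth.csv, excluded.csv
(reward-consumption frame ranges). Every CSV starts with a comment line
recording the seed so outputs are traceable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, load_config, save_config
from .trajectory import BehavioralBout


def _write_csv(df: pd.DataFrame, path: Path, seed) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def write_session(outdir, config: PipelineConfig, traj, bouts,
                  activity=None, truth=None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    save_config(config, outdir / "config.yaml")
    tdf = pd.DataFrame({"frame": np.arange(traj.n_frames), "t": traj.t,
                        "x": traj.x, "y": traj.y,
                        "hd": traj.hd if traj.hd is not None else np.nan})
    _write_csv(tdf, outdir / "trajectory.csv", seed)
    bdf = pd.DataFrame([{"object_id": b.object_id, "lap": b.lap_id,
                         "frame_start": b.start, "frame_end": b.end,
                         "label": b.label} for b in bouts])
    _write_csv(bdf, outdir / "bouts.csv", seed)
    if activity is not None:
        adf = pd.DataFrame(np.asarray(activity))
        adf.insert(0, "cell_id", np.arange(len(adf)))
        _write_csv(adf, outdir / "activity.csv", seed)
    if truth is not None:
        _write_csv(truth.cells, outdir / "ground_truth.csv", seed)
        edf = pd.DataFrame(truth.excluded_ranges or [],
                           columns=["frame_start", "frame_end"])
        _write_csv(edf, outdir / "excluded.csv", seed)
    return outdir


def read_session(indir) -> dict:
    """Read the raw pieces of a session bundle.

    Returns a dict with keys config, trajectory (DataFrame), bouts
    (DataFrame), labels ((object_id, lap) -> label), activity (ndarray or
    None), ground_truth (DataFrame or None), excluded_ranges (list).
    """
    indir = Path(indir)
    if not (indir / "trajectory.csv").exists():
        raise FileNotFoundError(f"missing trajectory file: "
                                f"{indir / 'trajectory.csv'}")
    out = {"config": load_config(indir / "config.yaml"),
           "trajectory": pd.read_csv(indir / "trajectory.csv", comment="#"),
           "bouts": pd.read_csv(indir / "bouts.csv", comment="#")}
    out["labels"] = {(int(r.object_id), int(r.lap)): r.label
                     for r in out["bouts"].itertuples()}
    apath = indir / "activity.csv"
    if apath.exists():
        adf = pd.read_csv(apath, comment="#")
        out["activity"] = adf.drop(columns=["cell_id"]).to_numpy(float)
    else:
        out["activity"] = None
    gpath = indir / "ground_truth.csv"
    out["ground_truth"] = pd.read_csv(gpath, comment="#") \
        if gpath.exists() else None
    epath = indir / "excluded.csv"
    if epath.exists():
        edf = pd.read_csv(epath, comment="#")
        out["excluded_ranges"] = [(int(s), int(e)) for s, e in
                                  zip(edf.frame_start, edf.frame_end)]
    else:
        out["excluded_ranges"] = []
    return out
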