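"""On-disk formats: flat binary signals with JSON sidecars, TSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ChannelInfo, Recording


def save_recording(rec: Recording, directory, name: str) -> None:
    """Write ``name.dat`` (float32 channels x time), sidecar and stimulus table."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rec.samples.astype(np.float32).tofile(d / f"{name}.dat")
    sidecar = {
        "fs": rec.fs,
        "units": "uV",
        "n_channels": rec.n_channels,
        "n_samples": int(rec.samples.shape[1]),
        "dtype": "float32",
        "channels": [{"name": c.name, "kind": c.kind, "region": c.region,
                      "neighbors": c.neighbors, "is_bad": c.is_bad,
                      "probe": c.probe, "contact": c.contact}
                     for c in rec.channels],
        "markers": rec.markers,
        "analysis_window": list(rec.analysis_window),
    }
    (d / f"{name}.json").write_text(json.dumps(sidecar, indent=1))
    rec.stimuli.to_csv(d / f"{name}.stimuli.tsv", sep="\t", index=False)


def load_recording(directory, name: str) -> Recording:
    d = Path(directory)
    meta = json.loads((d / f"{name}.json").read_text())
    samples = np.fromfile(d / f"{name}.dat", dtype=meta["dtype"]).reshape(
        meta["n_channels"], meta["n_samples"]).astype(float)
    channels = [ChannelInfo(name=c["name"], kind=c["kind"], region=c["region"],
                            neighbors=c["neighbors"], is_bad=c["is_bad"],
                            probe=c.get("probe"), contact=c.get("contact"))
                for c in meta["channels"]]
    stim_path = d / f"{name}.stimuli.tsv"
    stimuli = (pd.read_csv(stim_path, sep="\t") if stim_path.exists()
               and stim_path.stat().st_size > 1 else None)
    if stimuli is not None and "onset_s" not in stimuli.columns:
        stimuli = None
    return Recording(samples, meta["fs"], channels, stimuli=stimuli,
                     markers=meta.get("markers", {}),
                     analysis_window=tuple(meta["analysis_window"]))


def list_recordings(directory) -> list[str]:
    """Names of all recordings (sidecar stems) found in a directory."""
    return sorted(p.stem for p in Path(directory).glob("*.json")
                  if p.with_suffix(".dat").exists())


def save_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_ground_truth(gt, directory, name: str) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    gt.events.to_csv(d / f"{name}.truth.tsv", sep="\t", index=False)
    extra = {"spatial_profile": list(map(float, gt.spatial_profile)),
             "polarity": list(map(float, gt.polarity))}
    (d / f"{name}.truth.json").write_text(json.dumps(extra, indent=1))
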