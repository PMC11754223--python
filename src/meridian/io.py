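"""Delimited-text persistence of epoch waveforms via a trial manifest.

Each segment is one two-column file (time_s, amplitude_uv); a manifest
CSV maps files to (participant, group, orientation, sf, trial, segment).
Intended for interchange and small fixtures — full simulated studies
keep waveforms in memory and persist only the spectral per-trial table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterator, List, Tuple

import numpy as np
import pandas as pd

__all__ = ["write_trial_waveforms", "iter_manifest_trials"]

MANIFEST_COLUMNS = [
    "participant", "group", "orientation", "sf", "trial", "segment", "file"
]


def write_trial_waveforms(
    out_dir,
    trials: Dict[Tuple[str, str, str, float, int], List[np.ndarray]],
    fs: float,
    manifest_name: str = "manifest.csv",
) -> Path:
    """Write segment waveforms and their manifest; returns the manifest path.

    ``trials`` maps (participant, group, orientation, sf, trial_index) to
    the list of segment sample arrays.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for (pid, group, orientation, sf, trial), segments in sorted(trials.items()):
        for si, samples in enumerate(segments):
            fname = f"{pid}_{orientation}_{sf:g}cpd_t{trial}_s{si}.tsv"
            t = np.arange(len(samples)) / fs
            np.savetxt(
                out / fname,
                np.column_stack([t, samples]),
                delimiter="\t",
                header="time_s\tamplitude_uv",
                comments="",
            )
            rows.append({
                "participant": pid, "group": group, "orientation": orientation,
                "sf": sf, "trial": trial, "segment": si, "file": fname,
            })
    manifest = out / manifest_name
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def iter_manifest_trials(
    manifest_path,
) -> Iterator[Tuple[Tuple[str, str, str, float, int], List[np.ndarray], float]]:
    """Yield ((participant, group, orientation, sf, trial), segments, fs).

    The sampling rate is inferred from the time column of each segment
    file (median of the sample-interval reciprocals).
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    base = manifest_path.parent
    keys = ["participant", "group", "orientation", "sf", "trial"]
    for key, sub in df.groupby(keys, sort=True):
        segments = []
        fs = None
        for _, row in sub.sort_values("segment").iterrows():
            data = np.loadtxt(base / row["file"], delimiter="\t", skiprows=1)
            if data.ndim != 2 or data.shape[1] != 2 or len(data) < 2:
                raise ValueError(f"malformed waveform file {row['file']!r}")
            dt = np.diff(data[:, 0])
            fs = 1.0 / float(np.median(dt))
            segments.append(data[:, 1])
        yield tuple(key), segments, fs
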