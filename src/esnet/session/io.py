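"""Reading recordings from EDF or delimited matrices, plus TSV persistence."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import edf
from .types import Recording, validate_montage


def load_montage(path: str | Path) -> dict[str, str]:
    """Load a channel -> region map from JSON."""
    with open(path) as fh:
        montage = json.load(fh)
    if not isinstance(montage, dict):
        raise ValueError("montage JSON must be an object {channel: region}")
    return {str(k): str(v) for k, v in montage.items()}


def read_recording(path: str | Path, montage_path: str | Path,
                   average_ref: bool = True) -> Recording:
    """Load a recording from EDF or a delimited matrix with a JSON sidecar.

    Delimited input is a channels x samples TSV/CSV whose sidecar
    ``<path>.json`` holds ``{"rate": ..., "channel_names": [...]}``.
    Average re-referencing is applied by default.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        samples, rate, channel_names = edf.read_edf(path)
    elif suffix in {".tsv", ".csv", ".txt"}:
        delim = "," if suffix == ".csv" else "\t"
        samples = np.loadtxt(path, delimiter=delim, ndmin=2)
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing sidecar {sidecar}")
        with open(sidecar) as fh:
            meta = json.load(fh)
        rate = float(meta["rate"])
        channel_names = [str(c) for c in meta["channel_names"]]
    else:
        raise ValueError(f"unknown recording format: {path.name}")

    if not np.all(np.isfinite(samples)):
        raise ValueError(f"non-finite samples in {path.name}")

    montage = load_montage(montage_path)
    validate_montage(montage, channel_names)
    rec = Recording(np.asarray(samples, dtype=float), rate, channel_names,
                    {c: montage[c] for c in channel_names})
    return rec.average_reference() if average_ref else rec


def write_recording_tsv(path: str | Path, rec: Recording) -> None:
    """Write a recording as TSV plus its ``.json`` sidecar."""
    path = Path(path)
    np.savetxt(path, rec.samples, delimiter="\t", fmt="%.10g")
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump({"rate": rec.rate, "channel_names": rec.channel_names}, fh)


def write_montage(path: str | Path, montage: dict[str, str]) -> None:
    with open(path, "w") as fh:
        json.dump(montage, fh, indent=1, sort_keys=True)


def write_matrix_tsv(path: str | Path, values: np.ndarray,
                     channel_names: list[str]) -> None:
    """Square channel x channel matrix as TSV with a header row/column."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        fh.write("channel\t" + "\t".join(channel_names) + "\n")
        for name, row in zip(channel_names, values):
            fh.write(name + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = [line.rstrip("\n").split("\t")[1:] for line in fh]
    return np.array(rows, dtype=float), header
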