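"""The frames x identities table of whisker parameters -- the pipeline output.

Stored as dense arrays (``params`` is ``(n_frames, N, 4)`` holding rho,
theta, b, L; ``valid`` marks which entries exist) with fps and provenance
metadata.  Round-trips losslessly through HDF5 (primary) and a flat CSV
mirror (``frame, identity, rho, theta, b, L``) that external trackers can
also produce for scoring.  Angles are radians on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = ["TraceTable", "PARAM_NAMES"]

PARAM_NAMES = ("rho", "theta", "b", "length")
SCHEMA_VERSION = 1


@dataclass
class TraceTable:
    params: np.ndarray  # (n_frames, N, 4) float, NaN where invalid
    valid: np.ndarray  # (n_frames, N) bool
    fps: float = 1000.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.params = np.asarray(self.params, float)
        self.valid = np.asarray(self.valid, bool)
        if self.params.ndim != 3 or self.params.shape[2] != 4:
            raise ValueError("params must be (n_frames, N, 4)")
        if self.valid.shape != self.params.shape[:2]:
            raise ValueError("valid must be (n_frames, N)")

    @classmethod
    def empty(cls, n_frames: int, n_identities: int, fps: float = 1000.0,
              provenance: dict | None = None) -> "TraceTable":
        return cls(
            np.full((n_frames, n_identities, 4), np.nan),
            np.zeros((n_frames, n_identities), bool),
            fps=fps,
            provenance=provenance or {},
        )

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def n_identities(self) -> int:
        return self.params.shape[1]

    def set(self, frame: int, identity: int, values) -> None:
        self.params[frame, identity] = np.asarray(values, float)
        self.valid[frame, identity] = True

    def angle_trace(self, identity: int) -> np.ndarray:
        """theta series with NaN at missing frames."""
        out = self.params[:, identity, 1].copy()
        out[~self.valid[:, identity]] = np.nan
        return out

    # -- I/O -------------------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w", track_order=False) as f:
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.attrs["fps"] = float(self.fps)
            for k, v in sorted(self.provenance.items()):
                f.attrs[f"provenance_{k}"] = str(v)
            f.create_dataset("params", data=self.params, track_times=False)
            f.create_dataset("valid", data=self.valid, track_times=False)

    @classmethod
    def from_hdf5(cls, path) -> "TraceTable":
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("schema_version", -1))
            if version != SCHEMA_VERSION:
                raise ValueError(
                    f"unsupported trace schema version {version!r}"
                )
            prov = {
                k[len("provenance_"):]: str(v)
                for k, v in f.attrs.items()
                if k.startswith("provenance_")
            }
            return cls(
                f["params"][()],
                f["valid"][()],
                fps=float(f.attrs["fps"]),
                provenance=prov,
            )

    def to_csv(self, path) -> None:
        frames, idents = np.nonzero(self.valid)
        df = pd.DataFrame(
            {
                "frame": frames,
                "identity": idents,
                "rho": self.params[frames, idents, 0],
                "theta": self.params[frames, idents, 1],
                "b": self.params[frames, idents, 2],
                "length": self.params[frames, idents, 3],
            }
        )
        with open(path, "w", newline="") as fh:
            fh.write(f"# whiskertrack trace v{SCHEMA_VERSION} fps={self.fps}\n")
            df.to_csv(fh, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, n_frames: int | None = None,
                 n_identities: int | None = None) -> "TraceTable":
        with open(path) as fh:
            header = fh.readline()
            fps = 1000.0
            if header.startswith("#"):
                for tok in header.split():
                    if tok.startswith("fps="):
                        fps = float(tok[4:])
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        n_frames = n_frames or int(df["frame"].max()) + 1
        n_identities = n_identities or int(df["identity"].max()) + 1
        table = cls.empty(n_frames, n_identities, fps=fps)
        cols = ["rho", "theta", "b", "length"]
        table.params[df["frame"], df["identity"]] = df[cols].to_numpy()
        table.valid[df["frame"], df["identity"]] = True
        return table
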