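"""Video and trace file I/O.

Supported video sources: multi-page TIFF files and directories of numbered
PNG/TIFF frames, both decoded lazily to grayscale intensity arrays.  AVI and
other container formats require an ffmpeg-backed imageio plugin
(``imageio-ffmpeg``); without one, :func:`read_video` raises a clear error.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

__all__ = ["read_video", "write_traces", "read_traces", "TiffVideo", "FrameDirectory"]

_FRAME_SUFFIXES = {".png", ".tif", ".tiff"}


def _to_gray(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 3:
        frame = frame[..., :3].mean(axis=-1).astype(frame.dtype)
    return frame


class TiffVideo:
    """Lazy page-wise reader for a multi-page TIFF."""

    def __init__(self, path):
        self._tif = tifffile.TiffFile(str(path))
        self._n = len(self._tif.pages)
        if self._n == 0:
            raise ValueError(f"{path}: TIFF contains no pages")

    def __len__(self) -> int:
        return self._n

    def __getitem__(self, i: int) -> np.ndarray:
        if not 0 <= i < self._n:
            raise IndexError(i)
        return _to_gray(self._tif.pages[i].asarray())

    def __iter__(self):
        for i in range(self._n):
            yield self[i]


class FrameDirectory:
    """Directory of numbered image frames, sorted by filename."""

    def __init__(self, path):
        path = Path(path)
        self.files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
        )
        if not self.files:
            raise ValueError(f"{path}: no PNG/TIFF frames found")

    def __len__(self) -> int:
        return len(self.files)

    def __getitem__(self, i: int) -> np.ndarray:
        import imageio.v3 as iio

        return _to_gray(iio.imread(self.files[i]))

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


def read_video(path):
    """Open a video source as an indexable grayscale frame sequence."""
    path = Path(path)
    if path.is_dir():
        return FrameDirectory(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return TiffVideo(path)
    if suffix in (".avi", ".mp4", ".mov"):
        try:
            import imageio.v2 as iio

            reader = iio.get_reader(str(path))
            return [_to_gray(np.asarray(f)) for f in reader]
        except Exception as exc:  # no ffmpeg backend available
            raise RuntimeError(
                f"cannot decode {path.name}: container formats need an "
                "ffmpeg-backed imageio plugin (pip install imageio-ffmpeg)"
            ) from exc
    raise ValueError(f"unsupported video source: {path}")


def write_traces(trace, path) -> None:
    """Write a TraceTable; format chosen by suffix (.h5/.hdf5 or .csv)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        trace.to_hdf5(path)
    elif path.suffix.lower() == ".csv":
        trace.to_csv(path)
    else:
        raise ValueError(f"unsupported trace format: {path.suffix}")


def read_traces(path):
    from .trace import TraceTable

    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return TraceTable.from_hdf5(path)
    if path.suffix.lower() == ".csv":
        return TraceTable.from_csv(path)
    raise ValueError(f"unsupported trace format: {path.suffix}")
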