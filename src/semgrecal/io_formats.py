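"""Recording container, NinaPro-style MAT input, and the internal HDF5 dataset format.

A :class:`Recording` bundles a continuous multi-channel sEMG matrix with
per-sample movement labels (0 = rest) and per-sample repetition indices
(0 = rest). NinaPro DB2/DB3 distribute such recordings as MAT files with
``emg``, ``stimulus``/``restimulus`` and ``repetition``/``rerepetition``
variables; :func:`read_ninapro_mat` handles both the v5 and v7.3 (HDF5)
MAT dialects. Segmented/featurized data and recordings round-trip through
a small versioned HDF5 container via :func:`write_dataset` /
:func:`read_dataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import scipy.io

from .errors import AlignmentError, EmptySelectionError, FormatError, VersionError

SCHEMA_VERSION = 1

#: variable-name candidates per logical field, in preference order.
#: ``restimulus``/``rerepetition`` are the a-posteriori refined label streams
#: and are preferred when present.
DEFAULT_FIELD_MAP: Mapping[str, Sequence[str]] = {
    "emg": ("emg",),
    "labels": ("restimulus", "stimulus"),
    "repetition": ("rerepetition", "repetition"),
}


@dataclass
class Recording:
    """Continuous multichannel sEMG with aligned label and repetition streams.

    Attributes
    ----------
    emg : ndarray, shape (n_samples, n_channels)
        Raw signal, arbitrary units.
    fs : float
        Sampling rate in Hz.
    labels : ndarray of int, shape (n_samples,)
        Per-sample movement class; 0 denotes rest.
    repetition : ndarray of int, shape (n_samples,)
        Per-sample repetition index; 0 denotes rest.
    """

    emg: np.ndarray
    fs: float
    labels: np.ndarray
    repetition: np.ndarray
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=np.float64)
        if self.emg.ndim != 2:
            raise AlignmentError("emg must be a 2-D samples x channels matrix")
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
        self.repetition = np.asarray(self.repetition, dtype=np.int64).ravel()
        n = self.emg.shape[0]
        if len(self.labels) != n or len(self.repetition) != n:
            raise AlignmentError(
                f"stream lengths differ: emg {n}, labels {len(self.labels)}, "
                f"repetition {len(self.repetition)}"
            )
        if self.fs <= 0:
            raise AlignmentError("fs must be positive")
        if (self.labels < 0).any():
            raise AlignmentError("labels must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]

    @property
    def n_channels(self) -> int:
        return self.emg.shape[1]


def read_ninapro_mat(
    path,
    field_map: Mapping[str, Sequence[str]] | None = None,
    fs: float = 2000.0,
    subject_id: str = "",
    session_id: str = "",
) -> Recording:
    """Read a NinaPro-style MAT recording (v5 or v7.3).

    The ``field_map`` maps logical fields (``emg``, ``labels``,
    ``repetition``) to candidate variable names tried in order, which covers
    the DB2/DB3 ``stimulus`` vs ``restimulus`` dialect difference.
    """
    field_map = dict(DEFAULT_FIELD_MAP) | dict(field_map or {})
    variables = _load_mat_variables(path)

    def pick(logical: str) -> np.ndarray:
        candidates = field_map[logical]
        for name in candidates:
            if name in variables:
                return np.asarray(variables[name])
        raise FormatError(
            f"MAT file {path} is missing variable(s) {tuple(candidates)} "
            f"for field '{logical}'"
        )

    emg = pick("emg")
    if emg.ndim != 2:
        raise FormatError(f"emg variable must be 2-D, got shape {emg.shape}")
    # MAT v7.3 stores arrays transposed relative to the MATLAB shape
    if emg.shape[0] < emg.shape[1]:
        emg = emg.T
    labels = pick("labels").ravel()
    repetition = pick("repetition").ravel()
    try:
        return Recording(
            emg=emg, fs=fs, labels=labels, repetition=repetition,
            subject_id=subject_id, session_id=session_id,
        )
    except AlignmentError as exc:
        raise AlignmentError(f"{path}: {exc}") from exc


def _load_mat_variables(path) -> dict:
    try:
        data = scipy.io.loadmat(path)
        return {k: v for k, v in data.items() if not k.startswith("__")}
    except (NotImplementedError, ValueError):
        # MAT v7.3 is an HDF5 file (scipy cannot read it and raises)
        if not h5py.is_hdf5(path):
            raise FormatError(f"{path} is not a readable MAT file")
        out = {}
        with h5py.File(path, "r") as f:
            for k in f.keys():
                if isinstance(f[k], h5py.Dataset):
                    out[k] = f[k][()]
        return out


def split_by_repetition(recording: Recording, reps: Iterable[int]) -> Recording:
    """Extract the sub-recording belonging to the given repetition indices.

    Rest samples carry repetition 0 in NinaPro; each rest block is attached to
    the movement block that follows it, so every split retains rest-class
    data. Trailing rest (with no following movement) is attached to the
    preceding movement. Sample order is preserved.
    """
    reps = set(int(r) for r in reps)
    if not reps:
        raise EmptySelectionError("reps must be non-empty")
    rep = recording.repetition
    present = set(np.unique(rep[rep > 0]).tolist())
    if not (reps & present):
        raise EmptySelectionError(
            f"repetitions {sorted(reps)} not present; recording has {sorted(present)}"
        )
    effective = _attach_rest_to_following(rep)
    mask = np.isin(effective, list(reps))
    return replace(
        recording,
        emg=recording.emg[mask],
        labels=recording.labels[mask],
        repetition=recording.repetition[mask],
    )


def _attach_rest_to_following(rep: np.ndarray) -> np.ndarray:
    """Assign each rest sample (rep 0) the repetition of the next movement sample."""
    effective = rep.copy()
    movement_idx = np.flatnonzero(rep > 0)
    if movement_idx.size == 0:
        return effective
    rest_idx = np.flatnonzero(rep == 0)
    nxt = np.searchsorted(movement_idx, rest_idx)
    has_next = nxt < movement_idx.size
    effective[rest_idx[has_next]] = rep[movement_idx[nxt[has_next]]]
    # trailing rest: attach to the last movement
    effective[rest_idx[~has_next]] = rep[movement_idx[-1]]
    return effective


def write_dataset(obj, path) -> None:
    """Write a Recording or FeatureSet to the internal HDF5 container."""
    from .preprocessing import FeatureSet  # local import: avoids module cycle

    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if isinstance(obj, Recording):
            f.attrs["kind"] = "recording"
            f.create_dataset("emg", data=obj.emg)
            f.create_dataset("labels", data=obj.labels)
            f.create_dataset("repetition", data=obj.repetition)
            f.attrs["fs"] = obj.fs
            f.attrs["subject_id"] = obj.subject_id
            f.attrs["session_id"] = obj.session_id
        elif isinstance(obj, FeatureSet):
            f.attrs["kind"] = "featureset"
            f.create_dataset("scores", data=obj.scores)
            f.create_dataset("labels", data=obj.labels)
            f.create_dataset("repetitions", data=obj.repetitions)
            f.create_dataset("indices", data=obj.indices)
        else:
            raise TypeError(f"cannot serialize object of type {type(obj).__name__}")


def read_dataset(path):
    """Read back an object written by :func:`write_dataset`."""
    from .preprocessing import FeatureSet

    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise VersionError(
                f"{path}: schema version {version} is not supported "
                f"(this build reads version {SCHEMA_VERSION})"
            )
        kind = f.attrs["kind"]
        if kind == "recording":
            return Recording(
                emg=f["emg"][()],
                fs=float(f.attrs["fs"]),
                labels=f["labels"][()],
                repetition=f["repetition"][()],
                subject_id=str(f.attrs["subject_id"]),
                session_id=str(f.attrs["session_id"]),
            )
        if kind == "featureset":
            return FeatureSet(
                scores=f["scores"][()],
                labels=f["labels"][()],
                repetitions=f["repetitions"][()],
                indices=f["indices"][()],
            )
        raise FormatError(f"{path}: unknown dataset kind {kind!r}")
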