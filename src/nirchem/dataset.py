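"""Spectra container, wide-CSV I/O and calibration/prediction splitting.

The central object is :class:`SpectraSet`: an ``n_samples x n_bands``
absorbance matrix on a strictly increasing wavelength grid (nm), with
per-sample ids and optional origin labels and reference lipid contents (%).

The on-disk carrier is a wide CSV: first column the sample id, optional
``origin`` and ``lipid`` columns, and every remaining column header a
numeric wavelength in nm. Replicate rows sharing a sample id are averaged
on read (spectrometer practice of reading each sample several times).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, FormatError, LeakageError

__all__ = [
    "SpectraSet",
    "SplitPlan",
    "read_spectra",
    "write_spectra",
    "split_dataset",
    "make_folds",
]

_META_COLUMNS = ("origin", "lipid")


@dataclass
class SpectraSet:
    """Absorbance spectra plus per-sample reference data.

    Parameters
    ----------
    wavelengths : array of shape (n_bands,)
        Strictly increasing wavelength grid in nm.
    absorbance : array of shape (n_samples, n_bands)
        Unitless absorbance (or reflectance) values.
    sample_ids : sequence of str, unique
    origin : sequence of str or None
        Categorical origin label per sample (e.g. growing region).
    lipid : array or None
        Reference lipid content per sample in percent, each in (0, 100).
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: np.ndarray
    origin: np.ndarray | None = None
    lipid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.wavelengths.ndim != 1:
            raise FormatError("wavelengths must be one-dimensional")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise FormatError("wavelengths must be strictly increasing")
        n, p = self.absorbance.shape
        if p != self.wavelengths.size:
            raise FormatError(
                f"absorbance has {p} columns but grid has {self.wavelengths.size}"
            )
        if self.sample_ids.size != n:
            raise FormatError("sample_ids length must equal number of spectra")
        if len(set(self.sample_ids.tolist())) != n:
            raise ConsistencyError("sample_ids must be unique")
        if self.origin is not None:
            self.origin = np.asarray(self.origin, dtype=object)
            if self.origin.size != n:
                raise FormatError("origin length must equal number of samples")
        if self.lipid is not None:
            self.lipid = np.asarray(self.lipid, dtype=float)
            if self.lipid.size != n:
                raise FormatError("lipid length must equal number of samples")
            if np.any((self.lipid <= 0) | (self.lipid >= 100)):
                raise FormatError("lipid contents must lie in (0, 100) percent")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.absorbance.shape[1]

    def subset(self, indices: np.ndarray) -> "SpectraSet":
        """Row subset (copy) keeping grid and metadata alignment."""
        indices = np.asarray(indices, dtype=int)
        return SpectraSet(
            wavelengths=self.wavelengths.copy(),
            absorbance=self.absorbance[indices].copy(),
            sample_ids=self.sample_ids[indices].copy(),
            origin=None if self.origin is None else self.origin[indices].copy(),
            lipid=None if self.lipid is None else self.lipid[indices].copy(),
        )

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectraSet":
        """Same samples/grid with a replaced absorbance matrix."""
        return SpectraSet(
            wavelengths=self.wavelengths.copy(),
            absorbance=np.asarray(absorbance, dtype=float),
            sample_ids=self.sample_ids.copy(),
            origin=None if self.origin is None else self.origin.copy(),
            lipid=None if self.lipid is None else self.lipid.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide-CSV layout as a DataFrame (sample_id, origin?, lipid?, bands...)."""
        data: dict = {"sample_id": self.sample_ids}
        if self.origin is not None:
            data["origin"] = self.origin
        if self.lipid is not None:
            data["lipid"] = self.lipid
        frame = pd.DataFrame(data)
        spec = pd.DataFrame(
            self.absorbance, columns=[repr(float(w)) for w in self.wavelengths]
        )
        return pd.concat([frame, spec.set_index(frame.index)], axis=1)


@dataclass
class SplitPlan:
    """Fixed calibration/prediction split with optional k-fold assignment.

    ``fold_assignment`` holds a fold id in ``1..k`` for every calibration
    sample (aligned with ``calibration_indices``), or None before
    :func:`make_folds` has been applied.
    """

    calibration_indices: np.ndarray
    prediction_indices: np.ndarray
    seed: int
    fold_assignment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calibration_indices = np.asarray(self.calibration_indices, dtype=int)
        self.prediction_indices = np.asarray(self.prediction_indices, dtype=int)
        cal = set(self.calibration_indices.tolist())
        pred = set(self.prediction_indices.tolist())
        if cal & pred:
            raise LeakageError("calibration and prediction sets overlap")
        if len(cal) != self.calibration_indices.size:
            raise ConsistencyError("duplicate calibration indices")
        if len(pred) != self.prediction_indices.size:
            raise ConsistencyError("duplicate prediction indices")
        if self.fold_assignment is not None:
            self.fold_assignment = np.asarray(self.fold_assignment, dtype=int)
            if self.fold_assignment.size != self.calibration_indices.size:
                raise ConsistencyError("fold assignment length mismatch")

    @property
    def n_folds(self) -> int:
        if self.fold_assignment is None:
            return 0
        return int(self.fold_assignment.max())

    def iter_folds(self):
        """Yield (train_indices, validation_indices) into the full dataset,
        holding out each fold exactly once."""
        if self.fold_assignment is None:
            raise ValueError("no folds assigned; call make_folds first")
        for k in range(1, self.n_folds + 1):
            held = self.fold_assignment == k
            yield self.calibration_indices[~held], self.calibration_indices[held]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "calibration_indices": self.calibration_indices.tolist(),
            "prediction_indices": self.prediction_indices.tolist(),
            "seed": int(self.seed),
            "fold_assignment": None
            if self.fold_assignment is None
            else self.fold_assignment.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text())
        return cls(
            calibration_indices=np.asarray(payload["calibration_indices"]),
            prediction_indices=np.asarray(payload["prediction_indices"]),
            seed=payload["seed"],
            fold_assignment=None
            if payload["fold_assignment"] is None
            else np.asarray(payload["fold_assignment"]),
        )


def read_spectra(path: str | Path) -> SpectraSet:
    """Read a wide-CSV spectra file into a :class:`SpectraSet`.

    Replicate rows sharing a sample id are averaged (spectra and lipid);
    their origin labels must agree. The header of every non-metadata column
    must parse as a numeric wavelength in nm.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} is empty") from exc
    if frame.shape[1] < 2:
        raise FormatError(f"{path} has no spectral columns")
    id_col = frame.columns[0]
    meta_cols = [c for c in frame.columns[1:] if c in _META_COLUMNS]
    band_cols = [c for c in frame.columns[1:] if c not in _META_COLUMNS]
    try:
        wavelengths = np.array([float(c) for c in band_cols])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavelength header in {path}: {exc}") from exc

    ids, spectra, origins, lipids = [], [], [], []
    for sid, group in frame.groupby(id_col, sort=False):
        ids.append(str(sid))
        spectra.append(group[band_cols].to_numpy(dtype=float).mean(axis=0))
        if "origin" in meta_cols:
            labels = set(group["origin"].astype(str))
            if len(labels) > 1:
                raise ConsistencyError(
                    f"sample {sid!r} carries conflicting origin labels {sorted(labels)}"
                )
            origins.append(labels.pop())
        if "lipid" in meta_cols:
            lipids.append(float(group["lipid"].astype(float).mean()))

    return SpectraSet(
        wavelengths=wavelengths,
        absorbance=np.vstack(spectra),
        sample_ids=np.array(ids, dtype=object),
        origin=np.array(origins, dtype=object) if origins else None,
        lipid=np.array(lipids) if lipids else None,
    )


def write_spectra(data: SpectraSet, path: str | Path) -> None:
    """Write a :class:`SpectraSet` as wide CSV (UTF-8, '.' decimal).

    Floats are written with ``repr`` so a read-back round-trips exactly.
    """
    data.to_frame().to_csv(path, index=False)


def split_dataset(
    data: SpectraSet,
    n_calibration: int,
    n_prediction: int,
    stratify: bool = False,
    seed: int = 0,
) -> SplitPlan:
    """Random disjoint calibration/prediction split with fixed set sizes.

    With ``stratify`` the class proportions of ``data.origin`` are preserved
    to within one sample per class (largest-remainder allocation).
    """
    n = data.n_samples
    if n_calibration + n_prediction != n:
        raise ValueError(
            f"n_calibration + n_prediction = {n_calibration + n_prediction} != {n}"
        )
    if min(n_calibration, n_prediction) < 1:
        raise ValueError("both sets must be non-empty")
    rng = np.random.default_rng(seed)
    if not stratify:
        order = rng.permutation(n)
        cal, pred = order[:n_calibration], order[n_calibration:]
    else:
        if data.origin is None:
            raise ValueError("stratified split requires origin labels")
        cal_parts: list[np.ndarray] = []
        classes = list(dict.fromkeys(data.origin.tolist()))
        quota = {
            c: n_calibration * np.sum(data.origin == c) / n for c in classes
        }
        counts = {c: int(np.floor(quota[c])) for c in classes}
        remainder = sorted(
            classes, key=lambda c: (-(quota[c] - counts[c]), classes.index(c))
        )
        short = n_calibration - sum(counts.values())
        for c in remainder[:short]:
            counts[c] += 1
        for c in classes:
            members = np.flatnonzero(data.origin == c)
            members = rng.permutation(members)
            cal_parts.append(members[: counts[c]])
        cal = np.concatenate(cal_parts)
        pred = np.setdiff1d(np.arange(n), cal)
        cal, pred = rng.permutation(cal), rng.permutation(pred)
    return SplitPlan(
        calibration_indices=cal,
        prediction_indices=pred,
        seed=seed,
    )


def make_folds(plan: SplitPlan, k: int = 5, seed: int | None = None) -> SplitPlan:
    """Assign the calibration samples of ``plan`` to ``k`` random folds.

    Fold sizes differ by at most one; downstream cross-validation holds out
    each fold exactly once. Returns a new plan; ``plan`` is not modified.
    """
    n_cal = plan.calibration_indices.size
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n_cal:
        raise ValueError(f"k={k} exceeds the {n_cal} calibration samples")
    rng = np.random.default_rng(plan.seed if seed is None else seed)
    order = rng.permutation(n_cal)
    assignment = np.empty(n_cal, dtype=int)
    # round-robin over a random permutation -> sizes differ by <= 1
    assignment[order] = (np.arange(n_cal) % k) + 1
    return SplitPlan(
        calibration_indices=plan.calibration_indices.copy(),
        prediction_indices=plan.prediction_indices.copy(),
        seed=plan.seed,
        fold_assignment=assignment,
    )
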