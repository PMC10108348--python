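"""Domain types and tab-delimited readers/writers for snapshot-level
electronic-structure data and MM-GBSA frame tables.

A snapshot table carries, per molecular-dynamics configuration, the S1 (and
optionally S2) excitation energies together with the first-order transition
dipole vectors among the states involved.  Energies live in the files in eV
(declared by the ``_ev`` column suffix) and internally in hartree; dipoles
are in atomic units (e*a0) everywhere.

Left and right transition moments are kept as separate tables because
coupled-cluster response theory is non-Hermitian: the |0> -> |L> ("right")
and <L| <- <0| ("left") first-order moments generally differ.  A table
without ``muL_*`` columns is read as Hermitian data (left copied from
right, the manifold flagged accordingly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import HARTREE_EV
from .errors import (
    DuplicateRecordError,
    TableFormatError,
    TableParseError,
    UnknownStateError,
)

__all__ = [
    "DipoleVector",
    "StateManifold",
    "SnapshotRecord",
    "GbsaFrame",
    "manifold_from_pairs",
    "read_snapshot_table",
    "write_snapshot_table",
    "read_gbsa_table",
    "write_gbsa_table",
]

_FLOAT_FMT = "{:.12g}"


@dataclass(frozen=True)
class DipoleVector:
    """A dipole (or transition dipole) vector in atomic units (e*a0)."""

    x: float
    y: float
    z: float

    def __post_init__(self):
        for c in (self.x, self.y, self.z):
            if not math.isfinite(c):
                raise ValueError(f"dipole component not finite: {c!r}")

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "DipoleVector":
        x, y, z = (float(v) for v in arr)
        return cls(x, y, z)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def magnitude(self) -> float:
        return math.sqrt(self.x * self.x + self.y * self.y + self.z * self.z)


PairKey = tuple[str, str]


def _sym_pairs(pairs: Mapping[PairKey, DipoleVector]) -> dict[PairKey, DipoleVector]:
    """Expand an unordered pair table to both ordered orientations."""
    out: dict[PairKey, DipoleVector] = {}
    for (a, b), vec in pairs.items():
        out[(a, b)] = vec
        out.setdefault((b, a), vec)
    return out


@dataclass(frozen=True)
class StateManifold:
    """The electronic manifold of one snapshot.

    ``state_labels`` is ordered with the ground state "0" first; energies
    are excitation energies in hartree (ground fixed at 0).  Transition
    dipoles are stored per ordered pair of distinct states, once for the
    right and once for the left moments; state (permanent) dipoles are a
    separate per-state table.
    """

    state_labels: tuple[str, ...]
    energies: Mapping[str, float]
    state_dipoles: Mapping[str, DipoleVector]
    transition_dipoles_right: Mapping[PairKey, DipoleVector]
    transition_dipoles_left: Mapping[PairKey, DipoleVector]
    hermitian: bool = False

    def __post_init__(self):
        labels = self.state_labels
        if not labels or labels[0] != "0":
            raise ValueError("state_labels must start with the ground state '0'")
        if self.energies[labels[0]] != 0.0:
            raise ValueError("ground-state energy must be exactly 0")
        ens = [self.energies[s] for s in labels]
        if any(b <= a for a, b in zip(ens, ens[1:])):
            raise ValueError("excitation energies must increase with state index")
        for s in labels:
            if s not in self.state_dipoles:
                raise ValueError(f"missing state dipole for {s!r}")
        for a in labels:
            for b in labels:
                if a == b:
                    continue
                for table, name in (
                    (self.transition_dipoles_right, "right"),
                    (self.transition_dipoles_left, "left"),
                ):
                    if (a, b) not in table:
                        raise ValueError(f"missing {name} transition dipole ({a},{b})")
        if self.hermitian:
            for key, right in self.transition_dipoles_right.items():
                left = self.transition_dipoles_left[key]
                if left != right:
                    raise ValueError(
                        f"manifold flagged hermitian but left != right for {key}"
                    )

    def energy(self, state: str) -> float:
        try:
            return self.energies[state]
        except KeyError:
            raise UnknownStateError(f"unknown state label {state!r}") from None

    def dipole(self, bra: str, ket: str, side: str = "right") -> np.ndarray:
        """Dipole vector for the (bra, ket) pair as a numpy array.

        Diagonal pairs return the permanent state dipole regardless of
        ``side`` (there is a single permanent-dipole table).
        """
        for s in (bra, ket):
            if s not in self.energies:
                raise UnknownStateError(f"unknown state label {s!r}")
        if bra == ket:
            return self.state_dipoles[bra].as_array()
        table = (
            self.transition_dipoles_right
            if side == "right"
            else self.transition_dipoles_left
        )
        return table[(bra, ket)].as_array()

    def restricted(self, labels: Iterable[str]) -> "StateManifold":
        """Sub-manifold over ``labels`` (must include the ground state)."""
        keep = [s for s in self.state_labels if s in set(labels)]
        return StateManifold(
            state_labels=tuple(keep),
            energies={s: self.energies[s] for s in keep},
            state_dipoles={s: self.state_dipoles[s] for s in keep},
            transition_dipoles_right={
                k: v
                for k, v in self.transition_dipoles_right.items()
                if k[0] in keep and k[1] in keep
            },
            transition_dipoles_left={
                k: v
                for k, v in self.transition_dipoles_left.items()
                if k[0] in keep and k[1] in keep
            },
            hermitian=self.hermitian,
        )


def manifold_from_pairs(
    energies: Mapping[str, float],
    state_dipoles: Mapping[str, Sequence[float]],
    right: Mapping[PairKey, Sequence[float]],
    left: Mapping[PairKey, Sequence[float]] | None = None,
) -> StateManifold:
    """Build a :class:`StateManifold` from unordered pair tables.

    ``left=None`` marks Hermitian data: left moments are copied from the
    right table and the manifold is flagged ``hermitian``.
    """
    labels = tuple(sorted(energies, key=lambda s: energies[s]))
    right_vec = {k: DipoleVector.from_array(v) for k, v in right.items()}
    hermitian = left is None
    left_vec = (
        dict(right_vec)
        if left is None
        else {k: DipoleVector.from_array(v) for k, v in left.items()}
    )
    return StateManifold(
        state_labels=labels,
        energies=dict(energies),
        state_dipoles={s: DipoleVector.from_array(v) for s, v in state_dipoles.items()},
        transition_dipoles_right=_sym_pairs(right_vec),
        transition_dipoles_left=_sym_pairs(left_vec),
        hermitian=hermitian,
    )


@dataclass(frozen=True)
class SnapshotRecord:
    """One MD/QM-MM configuration's electronic manifold for one site."""

    site_id: str
    frame_index: int
    manifold: StateManifold

    def __post_init__(self):
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        labels = set(self.manifold.state_labels)
        if not {"0", "S1"} <= labels:
            raise ValueError("manifold must contain at least states 0 and S1")


@dataclass(frozen=True)
class GbsaFrame:
    """Per-frame MM-GBSA components, kcal/mol."""

    e_vdw: float
    e_elec: float
    g_gb: float
    g_sa: float

    def __post_init__(self):
        for v in (self.e_vdw, self.e_elec, self.g_gb, self.g_sa):
            if not math.isfinite(v):
                raise ValueError("GBSA components must be finite")


# ---------------------------------------------------------------------------
# Snapshot tables
# ---------------------------------------------------------------------------

_PAIR_OF_TAG = {"01": ("0", "S1"), "02": ("0", "S2"), "12": ("S1", "S2")}
_STATE_OF_TAG = {"00": "0", "11": "S1", "22": "S2"}


def _triplet(prefix: str) -> list[str]:
    return [f"{prefix}_{ax}" for ax in "xyz"]


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in required:
        if col not in df.columns:
            raise TableFormatError(f"missing required column {col!r} in {path}")
    return df


def _numeric(df: pd.DataFrame, columns: Iterable[str], path: Path) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() & out[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header line
            raise TableParseError(
                f"non-numeric value {out[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {row} of {path}"
            )
        out[col] = converted
    return out


def read_snapshot_table(path: str | Path) -> list[SnapshotRecord]:
    """Read a tab-delimited snapshot table into :class:`SnapshotRecord` s.

    Required columns: ``site``, ``frame``, ``e_s1_ev``, ``muR_01_{x,y,z}``,
    ``mu_00_{x,y,z}``, ``mu_11_{x,y,z}``.  ``e_s2_ev`` plus the 02/12 pair
    and ``mu_22`` triplets extend the manifold to S2.  Absent ``muL_*``
    columns imply Hermitian data.
    """
    path = Path(path)
    required = ["site", "frame", "e_s1_ev"]
    required += _triplet("muR_01") + _triplet("mu_00") + _triplet("mu_11")
    df = _read_table(path, required)

    has_s2 = "e_s2_ev" in df.columns
    pair_tags = ["01"] + (["02", "12"] if has_s2 else [])
    state_tags = ["00", "11"] + (["22"] if has_s2 else [])
    if has_s2:
        for tag in ("02", "12"):
            for col in _triplet(f"muR_{tag}"):
                if col not in df.columns:
                    raise TableFormatError(
                        f"missing required column {col!r} in {path} "
                        "(S2 energies present)"
                    )
        for col in _triplet("mu_22"):
            if col not in df.columns:
                raise TableFormatError(
                    f"missing required column {col!r} in {path} (S2 energies present)"
                )

    has_left = any(c.startswith("muL_") for c in df.columns)
    if has_left:
        for tag in pair_tags:
            for col in _triplet(f"muL_{tag}"):
                if col not in df.columns:
                    raise TableFormatError(
                        f"missing required column {col!r} in {path} "
                        "(left-moment columns are partial)"
                    )

    numeric_cols = [c for c in df.columns if c != "site"]
    df = _numeric(df, numeric_cols, path)

    seen: set[tuple[str, int]] = set()
    records: list[SnapshotRecord] = []
    for _, row in df.iterrows():
        site = str(row["site"])
        frame = int(row["frame"])
        key = (site, frame)
        if key in seen:
            raise DuplicateRecordError(
                f"duplicate (site, frame) = {key} in {path}"
            )
        seen.add(key)

        energies = {"0": 0.0, "S1": float(row["e_s1_ev"]) / HARTREE_EV}
        if has_s2:
            energies["S2"] = float(row["e_s2_ev"]) / HARTREE_EV

        def vec(prefix: str) -> tuple[float, float, float]:
            return tuple(float(row[c]) for c in _triplet(prefix))

        state_dipoles = {_STATE_OF_TAG[t]: vec(f"mu_{t}") for t in state_tags}
        right = {_PAIR_OF_TAG[t]: vec(f"muR_{t}") for t in pair_tags}
        left = (
            {_PAIR_OF_TAG[t]: vec(f"muL_{t}") for t in pair_tags}
            if has_left
            else None
        )
        manifold = manifold_from_pairs(energies, state_dipoles, right, left)
        records.append(SnapshotRecord(site, frame, manifold))
    return records


def write_snapshot_table(records: Sequence[SnapshotRecord], path: str | Path) -> None:
    """Write records with a deterministic column order and fixed formatting,
    so identical inputs produce byte-identical files."""
    path = Path(path)
    if records:
        first = records[0].manifold
        has_s2 = "S2" in first.state_labels
        has_left = not first.hermitian
        for rec in records:
            if ("S2" in rec.manifold.state_labels) != has_s2:
                raise ValueError("records mix S2-bearing and S2-free manifolds")
            if (not rec.manifold.hermitian) != has_left:
                raise ValueError("records mix Hermitian and non-Hermitian manifolds")
    else:
        has_s2 = False
        has_left = False

    pair_tags = ["01"] + (["02", "12"] if has_s2 else [])
    state_tags = ["00", "11"] + (["22"] if has_s2 else [])

    columns = ["site", "frame", "e_s1_ev"] + (["e_s2_ev"] if has_s2 else [])
    for tag in pair_tags:
        columns += _triplet(f"muR_{tag}")
        if has_left:
            columns += _triplet(f"muL_{tag}")
    for tag in state_tags:
        columns += _triplet(f"mu_{tag}")

    lines = ["\t".join(columns)]
    for rec in records:
        m = rec.manifold
        values: list[str] = [rec.site_id, str(rec.frame_index)]
        values.append(_FLOAT_FMT.format(m.energies["S1"] * HARTREE_EV))
        if has_s2:
            values.append(_FLOAT_FMT.format(m.energies["S2"] * HARTREE_EV))
        for tag in pair_tags:
            pair = _PAIR_OF_TAG[tag]
            for v in m.transition_dipoles_right[pair].as_array():
                values.append(_FLOAT_FMT.format(v))
            if has_left:
                for v in m.transition_dipoles_left[pair].as_array():
                    values.append(_FLOAT_FMT.format(v))
        for tag in state_tags:
            for v in m.state_dipoles[_STATE_OF_TAG[tag]].as_array():
                values.append(_FLOAT_FMT.format(v))
        lines.append("\t".join(values))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GBSA tables
# ---------------------------------------------------------------------------

_GBSA_COLUMNS = ["site", "frame", "e_vdw", "e_elec", "g_gb", "g_sa"]


def read_gbsa_table(path: str | Path) -> dict[str, list[GbsaFrame]]:
    """Read per-frame MM-GBSA components, grouped by site, order preserved."""
    path = Path(path)
    df = _read_table(path, _GBSA_COLUMNS)
    df = _numeric(df, [c for c in _GBSA_COLUMNS if c != "site"], path)
    seen: set[tuple[str, int]] = set()
    out: dict[str, list[GbsaFrame]] = {}
    for _, row in df.iterrows():
        site = str(row["site"])
        key = (site, int(row["frame"]))
        if key in seen:
            raise DuplicateRecordError(f"duplicate (site, frame) = {key} in {path}")
        seen.add(key)
        out.setdefault(site, []).append(
            GbsaFrame(
                float(row["e_vdw"]),
                float(row["e_elec"]),
                float(row["g_gb"]),
                float(row["g_sa"]),
            )
        )
    return out


def write_gbsa_table(frames: Mapping[str, Sequence[GbsaFrame]], path: str | Path) -> None:
    lines = ["\t".join(_GBSA_COLUMNS)]
    for site, site_frames in frames.items():
        for i, fr in enumerate(site_frames):
            vals = [site, str(i)] + [
                _FLOAT_FMT.format(v) for v in (fr.e_vdw, fr.e_elec, fr.g_gb, fr.g_sa)
            ]
            lines.append("\t".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")
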