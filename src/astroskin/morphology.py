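"""Astrocyte morphology containers and I/O.

An astrocyte skeleton is a hierarchy of *samples* (point + radius + parent
link), grouped into *segments* (consecutive sample pairs), *sections* (maximal
unbranched chains of segments) and *arbors* (rooted acyclic section trees
emanating from a single soma sample).  Perivascular *endfeet* are stored
separately as open triangle patches with a per-vertex thickness.

Arbors are read from standard 7-column SWC; endfeet travel in a sidecar file
(HDF5 container or plain JSON, schema version ``astroskin_endfeet_v1``).
All coordinates and radii are micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional

import numpy as np


class StructureType(Enum):
    """SWC-style process classification.

    SWC type codes map as 1 -> soma, 3 -> perivascular (dendrite-like),
    2 -> perisynaptic (axon-like); every other code is a generic neurite.
    """

    SOMA = "soma"
    PERIVASCULAR_PROCESS = "perivascular_process"
    PERISYNAPTIC_PROCESS = "perisynaptic_process"
    GENERIC_NEURITE = "generic_neurite"


_SWC_TO_STRUCTURE = {
    1: StructureType.SOMA,
    2: StructureType.PERISYNAPTIC_PROCESS,
    3: StructureType.PERIVASCULAR_PROCESS,
}
_STRUCTURE_TO_SWC = {
    StructureType.SOMA: 1,
    StructureType.PERISYNAPTIC_PROCESS: 2,
    StructureType.PERIVASCULAR_PROCESS: 3,
    StructureType.GENERIC_NEURITE: 5,
}

ENDFEET_FORMAT_VERSION = "astroskin_endfeet_v1"


class MorphologyError(ValueError):
    """Malformed or invalid morphology data."""


class SWCParseError(MorphologyError):
    """Unreadable SWC line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass
class Sample:
    """One skeleton point: position (µm), radius (µm), parent link, type."""

    id: int
    position: np.ndarray
    radius: float
    parent_id: Optional[int]
    structure_type: StructureType = StructureType.GENERIC_NEURITE

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise MorphologyError(f"sample {self.id}: position must be 3-d")
        if not self.radius > 0:
            raise MorphologyError(f"sample {self.id}: radius must be > 0")


@dataclass
class Section:
    """Maximal unbranched chain of samples.

    A non-root section shares its first sample with the last sample of its
    parent section (the branch point).  Root sections start at the first
    arbor sample; the connection back to the soma is the *somatic segment*
    and is handled by the soma skinner, not stored here.
    """

    samples: list[Sample]
    parent_section: Optional["Section"] = None
    child_sections: list["Section"] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.samples) - 1

    def polyline(self) -> np.ndarray:
        return np.array([s.position for s in self.samples])

    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.samples])

    def length(self) -> float:
        pts = self.polyline()
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


@dataclass
class Arbor:
    """Rooted acyclic tree of sections emanating from the soma."""

    root_section: Section

    def sections(self) -> Iterator[Section]:
        """Depth-first iteration over the section tree."""
        stack = [self.root_section]
        while stack:
            sec = stack.pop()
            yield sec
            stack.extend(reversed(sec.child_sections))

    @property
    def root_sample(self) -> Sample:
        return self.root_section.samples[0]

    def samples(self) -> Iterator[Sample]:
        """Every sample exactly once (branch samples yielded by their owner)."""
        for sec in self.sections():
            start = 0 if sec.parent_section is None else 1
            yield from sec.samples[start:]

    def n_sections(self) -> int:
        return sum(1 for _ in self.sections())

    def cable_length(self) -> float:
        return sum(sec.length() for sec in self.sections())

    def max_branch_order(self) -> int:
        order = 0
        stack = [(self.root_section, 1)]
        while stack:
            sec, o = stack.pop()
            order = max(order, o)
            stack.extend((c, o + 1) for c in sec.child_sections)
        return order


@dataclass
class EndfootPatch:
    """Open 2-manifold triangle patch with per-vertex thickness (µm)."""

    vertices: np.ndarray  # (N, 3) float
    thickness: np.ndarray  # (N,) float, > 0
    triangles: np.ndarray  # (M, 3) int, 0-based

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.thickness = np.asarray(self.thickness, dtype=float).ravel()
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)

    def validate(self) -> None:
        n = len(self.vertices)
        if len(self.thickness) != n:
            raise MorphologyError(
                f"thickness count {len(self.thickness)} != vertex count {n}"
            )
        if np.any(self.thickness <= 0):
            raise MorphologyError("endfoot thickness values must be > 0")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= n
        ):
            raise MorphologyError("triangle index out of range")
        counts = _edge_face_counts(self.triangles)
        if np.any(counts > 2):
            raise MorphologyError(
                "endfoot patch is non-manifold: an edge has >2 incident triangles"
            )

    def edge_lengths(self) -> np.ndarray:
        edges = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        return np.linalg.norm(
            self.vertices[edges[:, 0]] - self.vertices[edges[:, 1]], axis=1
        )


def _edge_face_counts(triangles: np.ndarray) -> np.ndarray:
    edges = np.vstack(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
    )
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return counts


@dataclass
class AstrocyteMorphology:
    """Single-sample soma + arbors + endfeet patches."""

    soma: Sample
    arbors: list[Arbor]
    endfeet: list[EndfootPatch] = field(default_factory=list)

    def samples(self) -> Iterator[Sample]:
        yield self.soma
        for arbor in self.arbors:
            yield from arbor.samples()

    def n_samples(self) -> int:
        return sum(1 for _ in self.samples())

    def n_sections(self) -> int:
        return sum(a.n_sections() for a in self.arbors)

    def total_segment_count(self) -> int:
        """All segments, including the somatic segment that joins the soma
        to each arbor's first sample."""
        return (
            sum(sec.n_segments for a in self.arbors for sec in a.sections())
            + len(self.arbors)
        )

    def min_radius(self) -> float:
        return min(s.radius for s in self.samples())


# ---------------------------------------------------------------------------
# SWC reading / writing


def _build_sections(
    samples: dict[int, Sample], children: dict[int, list[int]], soma_id: int
) -> list[Arbor]:
    """Group non-soma samples into maximal unbranched sections."""

    def chain_from(first_id: int, parent_sec: Optional[Section]) -> Section:
        chain = []
        if parent_sec is not None:
            chain.append(parent_sec.samples[-1])  # shared branch sample
        cur = first_id
        while True:
            chain.append(samples[cur])
            kids = children.get(cur, [])
            if len(kids) != 1:
                break
            cur = kids[0]
        sec = Section(samples=chain, parent_section=parent_sec)
        for kid in children.get(cur, []):
            child = chain_from(kid, sec)
            sec.child_sections.append(child)
        return sec

    arbors = []
    for root_id in children.get(soma_id, []):
        arbors.append(Arbor(root_section=chain_from(root_id, None)))
    return arbors


def read_swc(path: str | Path) -> AstrocyteMorphology:
    """Read a whitespace-delimited 7-column SWC file.

    Raises :class:`SWCParseError` for malformed lines and
    :class:`MorphologyError` for structural defects (multiple roots, cycles,
    dangling parents).  The endfeet list of the result is empty.
    """
    samples: dict[int, Sample] = {}
    parent_of: dict[int, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(f"expected 7 columns, got {len(parts)}", lineno)
            try:
                sid = int(parts[0])
                stype = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                pid = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(str(exc), lineno) from None
            if sid in samples:
                raise SWCParseError(f"duplicate sample id {sid}", lineno)
            if r <= 0:
                raise SWCParseError(f"sample {sid}: radius {r} is not > 0", lineno)
            samples[sid] = Sample(
                id=sid,
                position=np.array([x, y, z]),
                radius=r,
                parent_id=None if pid == -1 else pid,
                structure_type=_SWC_TO_STRUCTURE.get(
                    stype, StructureType.GENERIC_NEURITE
                ),
            )
            if pid != -1:
                parent_of[sid] = pid

    if not samples:
        raise MorphologyError(f"{path}: no samples")

    roots = [s for s in samples.values() if s.parent_id is None]
    if len(roots) != 1:
        raise MorphologyError(f"expected exactly one root sample, found {len(roots)}")
    soma = roots[0]
    soma.structure_type = StructureType.SOMA

    # dangling parents and cycles
    children: dict[int, list[int]] = {}
    for sid, pid in parent_of.items():
        if pid not in samples:
            raise MorphologyError(f"sample {sid}: parent {pid} does not exist")
        children.setdefault(pid, []).append(sid)
    for sid in samples:
        seen = set()
        cur = sid
        while cur is not None:
            if cur in seen:
                raise MorphologyError(f"cycle in parent links at sample {cur}")
            seen.add(cur)
            cur = samples[cur].parent_id
    for kids in children.values():
        kids.sort()

    arbors = _build_sections(samples, children, soma.id)
    return AstrocyteMorphology(soma=soma, arbors=arbors, endfeet=[])


def write_swc(m: AstrocyteMorphology, path: str | Path) -> None:
    """Write arbors + soma as 7-column SWC, preserving sample ids."""
    lines = ["# written by astroskin", "# id type x y z radius parent"]

    def fmt(s: Sample) -> str:
        pid = -1 if s.parent_id is None else s.parent_id
        t = _STRUCTURE_TO_SWC[s.structure_type]
        x, y, z = s.position
        return f"{s.id} {t} {x:.17g} {y:.17g} {z:.17g} {s.radius:.17g} {pid}"

    lines.append(fmt(m.soma))
    for arbor in m.arbors:
        for s in arbor.samples():
            lines.append(fmt(s))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Endfeet sidecar


def write_endfeet_sidecar(patches: list[EndfootPatch], path: str | Path) -> None:
    """Write endfeet patches to a sidecar file.

    ``.h5``/``.hdf5`` extensions select the HDF5 container (one group per
    patch holding ``vertices[N,3]``, ``thickness[N]``, ``triangles[M,3]``,
    0-based indices); anything else gets the equivalent JSON layout.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["format"] = ENDFEET_FORMAT_VERSION
            for i, p in enumerate(patches):
                g = fh.create_group(f"endfoot_{i:04d}")
                g.create_dataset("vertices", data=p.vertices)
                g.create_dataset("thickness", data=p.thickness)
                g.create_dataset("triangles", data=p.triangles)
    else:
        doc = {
            "format": ENDFEET_FORMAT_VERSION,
            "endfeet": [
                {
                    "vertices": p.vertices.tolist(),
                    "thickness": p.thickness.tolist(),
                    "triangles": p.triangles.tolist(),
                }
                for p in patches
            ],
        }
        path.write_text(json.dumps(doc))


def read_endfeet_sidecar(path: str | Path) -> list[EndfootPatch]:
    """Read and validate endfeet patches from a sidecar file."""
    path = Path(path)
    patches: list[EndfootPatch] = []
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            version = fh.attrs.get("format")
            if version != ENDFEET_FORMAT_VERSION:
                raise MorphologyError(
                    f"unknown endfeet sidecar format {version!r}"
                )
            for name in sorted(fh.keys()):
                g = fh[name]
                patches.append(
                    EndfootPatch(
                        vertices=g["vertices"][...],
                        thickness=g["thickness"][...],
                        triangles=g["triangles"][...],
                    )
                )
    else:
        doc = json.loads(path.read_text())
        if doc.get("format") != ENDFEET_FORMAT_VERSION:
            raise MorphologyError(
                f"unknown endfeet sidecar format {doc.get('format')!r}"
            )
        for entry in doc["endfeet"]:
            patches.append(
                EndfootPatch(
                    vertices=np.array(entry["vertices"], dtype=float),
                    thickness=np.array(entry["thickness"], dtype=float),
                    triangles=np.array(entry["triangles"], dtype=np.int64),
                )
            )
    for p in patches:
        p.validate()
    return patches


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    violations: list[str]
    min_radius: float
    n_samples: int
    n_sections: int
    n_endfeet: int

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_morphology(m: AstrocyteMorphology) -> ValidationReport:
    """Report-only check of every structural invariant."""
    violations: list[str] = []

    if m.soma.parent_id is not None:
        violations.append(f"soma sample {m.soma.id} has a parent")
    seen_ids: dict[int, Sample] = {}
    for s in m.samples():
        if not s.radius > 0:
            violations.append(f"sample {s.id}: radius {s.radius} not > 0")
        if s.id in seen_ids:
            violations.append(f"duplicate sample id {s.id}")
        seen_ids[s.id] = s
    for s in m.samples():
        if s.parent_id is not None and s.parent_id not in seen_ids:
            violations.append(f"sample {s.id}: parent {s.parent_id} missing")

    for ai, arbor in enumerate(m.arbors):
        for sec in arbor.sections():
            if len(sec.samples) < 2:
                violations.append(f"arbor {ai}: section with <2 samples")
            for child in sec.child_sections:
                if child.samples[0] is not sec.samples[-1]:
                    violations.append(
                        f"arbor {ai}: child section does not share branch sample"
                    )

    for ei, patch in enumerate(m.endfeet):
        try:
            patch.validate()
        except MorphologyError as exc:
            violations.append(f"endfoot {ei}: {exc}")

    radii = [s.radius for s in m.samples()]
    return ValidationReport(
        violations=violations,
        min_radius=min(radii),
        n_samples=len(radii),
        n_sections=m.n_sections(),
        n_endfeet=len(m.endfeet),
    )
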