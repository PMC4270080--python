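"""Synthetic neuron morphologies: generation, SWC interchange, and arbor metrics.

Hippocampal CA1 and CA2 pyramidal neurons differ sharply in apical architecture:
CA1 cells send a single apical trunk to the stratum radiatum / stratum
lacunosum-moleculare border (~400 µm) before splitting into a fine tuft, while
CA2 cells split within 50-100 µm of the soma into many (~12) secondary branches
that each run independently into SLM.  This module generates parameterized
morphologies of either class so that spike-propagation experiments can be run
without access to proprietary reconstructions.

Conventions
-----------
* All lengths and diameters in micrometres.
* Electrical rules elsewhere in the package use *path distance* (arc length
  along the tree from the soma centre); Sholl analysis uses *Euclidean* radius
  from the soma centre, as in the standard anatomical method.
* The 3-D embedding is cosmetic: cable electrical behaviour depends only on
  lengths and diameters, so generators lay branches on a planar fan.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = [
    "Point3D",
    "Section",
    "Morphology",
    "MorphogenParams",
    "ShollProfile",
    "MorphologyError",
    "SWCParseError",
    "generate_morphology",
    "read_swc",
    "write_swc",
    "path_distance",
    "sholl",
    "branches_at_distance",
]

CATEGORIES = (
    "soma",
    "apical_trunk",
    "apical_secondary",
    "apical_tuft",
    "apical_oblique",
    "basal",
)
APICAL_CATEGORIES = ("apical_trunk", "apical_secondary", "apical_tuft", "apical_oblique")

# SWC type codes: 1 soma, 3 basal dendrite, 4 apical dendrite.  SWC has no
# apical sub-types, so the fine-grained category is preserved in a JSON sidecar.
_CATEGORY_TO_SWC = {"soma": 1, "basal": 3}
_SWC_TO_CATEGORY = {1: "soma", 2: "apical_trunk", 3: "basal", 4: "apical_trunk"}
for _c in APICAL_CATEGORIES:
    _CATEGORY_TO_SWC[_c] = 4


class MorphologyError(ValueError):
    """Structural problem in a morphology (disconnected, bad parent, ...)."""


class SWCParseError(MorphologyError):
    """Malformed SWC content; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class Point3D:
    """A 3-D sample point with local diameter (µm)."""

    x: float
    y: float
    z: float
    diameter: float

    def __post_init__(self):
        for name in ("x", "y", "z", "diameter"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError("Point3D coordinates/diameter must be finite")
            object.__setattr__(self, name, v)
        if self.diameter <= 0:
            raise ValueError(f"Point3D diameter must be > 0, got {self.diameter}")

    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Section:
    """An unbranched neurite stretch: an ordered run of sample points.

    ``parent`` is ``None`` for the soma, else ``(parent_id, fraction)`` where
    fraction in [0, 1] gives the attachment point along the parent's arc.
    """

    id: str
    category: str
    points: list[Point3D]
    parent: Optional[tuple[str, float]] = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown section category {self.category!r}")
        if self.category != "soma" and len(self.points) < 2:
            raise ValueError(f"section {self.id}: needs >= 2 points")
        if self.category == "soma" and self.parent is not None:
            raise ValueError("soma section cannot have a parent")
        if self.parent is not None:
            frac = self.parent[1]
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"attachment fraction {frac} outside [0, 1]")

    @property
    def length(self) -> float:
        """Total arc length (µm)."""
        return float(self.arc_lengths()[-1]) if len(self.points) > 1 else 0.0

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each point, starting at 0."""
        pts = np.array([[p.x, p.y, p.z] for p in self.points])
        if len(pts) < 2:
            return np.zeros(1)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def point_at(self, fraction: float) -> Point3D:
        """Interpolated point at the given arc-length fraction."""
        arcs = self.arc_lengths()
        target = fraction * arcs[-1]
        i = int(np.searchsorted(arcs, target, side="right") - 1)
        i = min(i, len(arcs) - 2) if len(arcs) > 1 else 0
        if len(arcs) == 1 or arcs[i + 1] == arcs[i]:
            return self.points[i]
        t = (target - arcs[i]) / (arcs[i + 1] - arcs[i])
        a, b = self.points[i], self.points[i + 1]
        return Point3D(
            a.x + t * (b.x - a.x),
            a.y + t * (b.y - a.y),
            a.z + t * (b.z - a.z),
            a.diameter + t * (b.diameter - a.diameter),
        )


@dataclass
class Morphology:
    """A connected, acyclic collection of sections rooted at one soma."""

    sections: dict[str, Section]
    root: str

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.root not in self.sections:
            raise MorphologyError(f"root section {self.root!r} missing")
        if self.sections[self.root].category != "soma":
            raise MorphologyError("root section must have category 'soma'")
        n_roots = 0
        for sec in self.sections.values():
            if sec.parent is None:
                n_roots += 1
                if sec.id != self.root:
                    raise MorphologyError(f"section {sec.id} has no parent but is not root")
            elif sec.parent[0] not in self.sections:
                raise MorphologyError(
                    f"section {sec.id}: parent {sec.parent[0]!r} does not resolve"
                )
        if n_roots != 1:
            raise MorphologyError(f"expected exactly one root, found {n_roots}")
        # connectivity + acyclicity: walk up from every section
        for sec in self.sections.values():
            seen = set()
            cur = sec
            while cur.parent is not None:
                if cur.id in seen:
                    raise MorphologyError(f"cycle through section {cur.id}")
                seen.add(cur.id)
                cur = self.sections[cur.parent[0]]
            if cur.id != self.root:
                raise MorphologyError(f"section {sec.id} not connected to root")

    def children_of(self, section_id: str) -> list[Section]:
        return sorted(
            (s for s in self.sections.values() if s.parent and s.parent[0] == section_id),
            key=lambda s: s.id,
        )

    @property
    def total_length(self) -> float:
        """Sum of point-wise arc lengths over all non-soma sections (µm)."""
        return float(sum(s.length for s in self.sections.values() if s.category != "soma"))

    def soma_center(self) -> np.ndarray:
        pts = np.array([[p.x, p.y, p.z] for p in self.sections[self.root].points])
        return pts.mean(axis=0)

    def ordered_sections(self) -> list[Section]:
        """Sections in a deterministic parent-before-child order."""
        out, todo = [], [self.sections[self.root]]
        while todo:
            sec = todo.pop(0)
            out.append(sec)
            todo.extend(self.children_of(sec.id))
        return out


@dataclass
class ShollProfile:
    """Counts of dendrite crossings of concentric spheres around the soma."""

    radii: list[float]
    intersections: list[int]

    def __post_init__(self):
        if len(self.radii) != len(self.intersections):
            raise ValueError("radii and intersections must have equal length")
        if any(c < 0 for c in self.intersections):
            raise ValueError("intersection counts must be >= 0")


@dataclass
class MorphogenParams:
    """Parameters of the synthetic-morphology generator.

    Defaults encode the two cell classes: ``ca2`` splits its apical trunk into
    ``n_secondary`` independent branches within ``trunk_split_distance`` of the
    soma (drawn uniformly in [50, 100] µm when left ``None``); ``ca1`` runs a
    single trunk to ``trunk_length_to_tuft`` (~400 µm, the SR/SLM border)
    before branching into a fine tuft.
    """

    cell_class: str = "ca2"  # {"ca1", "ca2"}
    trunk_split_distance: Optional[float] = None  # CA2; None => draw U[50, 100]
    n_secondary: int = 12  # CA2 secondary branch count
    trunk_length_to_tuft: float = 400.0  # CA1 trunk length to tuft origin
    total_apical_extent: float = 600.0  # soma-to-tip path length of every route
    tuft_start: float = 450.0  # CA2: path distance where secondaries become tuft-calibre
    branch_distance_band: float = 300.0  # centre of the per-branch stimulation band
    n_tuft_branches: int = 4  # CA1 terminal (tertiary) tuft branch count
    trunk_diameter: float = 2.5
    trunk_taper_to: float = 2.5  # CA1 trunk end diameter (uniform by default)
    secondary_diameter: float = 1.0
    tuft_diameter: float = 0.5
    soma_diameter: float = 15.0
    n_basal: int = 4
    basal_length: float = 150.0
    basal_diameter: float = 1.0
    fan_half_angle_deg: float = 55.0
    seed: int = 0

    def validate(self) -> None:
        if self.cell_class not in ("ca1", "ca2"):
            raise ValueError(f"cell_class must be 'ca1' or 'ca2', got {self.cell_class!r}")
        if self.n_secondary < 1:
            raise ValueError(f"n_secondary must be >= 1, got {self.n_secondary}")
        if self.total_apical_extent <= 400:
            raise ValueError(
                f"total_apical_extent must exceed 400 um so that distal synaptic "
                f"territory exists, got {self.total_apical_extent}"
            )
        for name in (
            "trunk_length_to_tuft",
            "tuft_start",
            "branch_distance_band",
            "trunk_diameter",
            "secondary_diameter",
            "tuft_diameter",
            "soma_diameter",
            "basal_length",
            "basal_diameter",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.trunk_split_distance is not None and self.trunk_split_distance <= 0:
            raise ValueError(
                f"trunk_split_distance must be > 0, got {self.trunk_split_distance}"
            )


def _section_points(
    origin: np.ndarray,
    direction: np.ndarray,
    length: float,
    d_start: float,
    d_end: float,
    n_pts: int = 5,
) -> list[Point3D]:
    direction = direction / np.linalg.norm(direction)
    ts = np.linspace(0.0, 1.0, n_pts)
    return [
        Point3D(*(origin + t * length * direction), d_start + t * (d_end - d_start))
        for t in ts
    ]


def generate_morphology(params: MorphogenParams) -> Morphology:
    """Generate a synthetic CA1-like or CA2-like pyramidal-cell morphology.

    Deterministic for identical ``params`` (including ``seed``).  The apical
    arbor is laid out as a planar fan in the +y half-plane; basal dendrites
    fan into -y.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    sections: dict[str, Section] = {}
    r_soma = params.soma_diameter / 2.0
    # sphere-equivalent cylinder: length == diameter gives equal surface area
    sections["soma"] = Section(
        id="soma",
        category="soma",
        points=[
            Point3D(0.0, -r_soma, 0.0, params.soma_diameter),
            Point3D(0.0, r_soma, 0.0, params.soma_diameter),
        ],
    )
    apex = np.array([0.0, r_soma, 0.0])
    up = np.array([0.0, 1.0, 0.0])

    if params.cell_class == "ca2":
        split = params.trunk_split_distance
        if split is None:
            split = float(rng.uniform(50.0, 100.0))
        if not split < params.tuft_start < params.total_apical_extent:
            raise ValueError(
                "require trunk_split_distance < tuft_start < total_apical_extent"
            )
        sections["apical_trunk"] = Section(
            id="apical_trunk",
            category="apical_trunk",
            points=_section_points(
                apex, up, split, params.trunk_diameter, params.trunk_diameter * 0.8
            ),
            parent=("soma", 1.0),
        )
        tip = apex + split * up
        angles = np.linspace(
            -params.fan_half_angle_deg, params.fan_half_angle_deg, params.n_secondary
        )
        for i, ang in enumerate(angles):
            rad = math.radians(ang)
            direction = np.array([math.sin(rad), math.cos(rad), 0.0])
            sec_id = f"apical_secondary_{i:02d}"
            sec_len = params.tuft_start - split
            sections[sec_id] = Section(
                id=sec_id,
                category="apical_secondary",
                points=_section_points(
                    tip, direction, sec_len, params.secondary_diameter,
                    params.secondary_diameter,
                ),
                parent=("apical_trunk", 1.0),
            )
            tuft_id = f"apical_tuft_{i:02d}"
            tuft_len = params.total_apical_extent - params.tuft_start
            sections[tuft_id] = Section(
                id=tuft_id,
                category="apical_tuft",
                points=_section_points(
                    tip + sec_len * direction, direction, tuft_len,
                    params.tuft_diameter, params.tuft_diameter,
                ),
                parent=(sec_id, 1.0),
            )
    else:  # ca1
        trunk_len = params.trunk_length_to_tuft
        if trunk_len >= params.total_apical_extent:
            raise ValueError("trunk_length_to_tuft must be < total_apical_extent")
        sections["apical_trunk"] = Section(
            id="apical_trunk",
            category="apical_trunk",
            points=_section_points(
                apex, up, trunk_len, params.trunk_diameter, params.trunk_taper_to,
                n_pts=9,
            ),
            parent=("soma", 1.0),
        )
        # fine tuft: a two-level binary cascade of secondary then tertiary
        # branches (per-junction convergence of 2, unlike the CA2 hot spot
        # where ~12 routes meet at one proximal branch point)
        tip = apex + trunk_len * up
        tuft_len = params.total_apical_extent - trunk_len
        n_term = max(2, 2 * (params.n_tuft_branches // 2))
        level1_angles = np.linspace(-params.fan_half_angle_deg / 2,
                                    params.fan_half_angle_deg / 2, 2)
        term_angles = np.linspace(-params.fan_half_angle_deg,
                                  params.fan_half_angle_deg, n_term)
        half = tuft_len / 2.0
        for i, ang in enumerate(level1_angles):
            rad = math.radians(ang)
            direction = np.array([math.sin(rad), math.cos(rad), 0.0])
            l1_id = f"apical_tuft_{i:02d}"
            sections[l1_id] = Section(
                id=l1_id,
                category="apical_tuft",
                points=_section_points(
                    tip, direction, half, params.tuft_diameter * 1.4,
                    params.tuft_diameter * 1.4,
                ),
                parent=("apical_trunk", 1.0),
            )
            l1_tip = tip + half * direction
            for j in range(n_term // 2):
                t_idx = i * (n_term // 2) + j
                rad_t = math.radians(term_angles[t_idx])
                dir_t = np.array([math.sin(rad_t), math.cos(rad_t), 0.0])
                term_id = f"apical_tuft_t{t_idx:02d}"
                sections[term_id] = Section(
                    id=term_id,
                    category="apical_tuft",
                    points=_section_points(
                        l1_tip, dir_t, half, params.tuft_diameter, params.tuft_diameter
                    ),
                    parent=(l1_id, 1.0),
                )

    # basal fan into -y
    base = np.array([0.0, -r_soma, 0.0])
    if params.n_basal > 0:
        angles = np.linspace(-50.0, 50.0, params.n_basal)
        for i, ang in enumerate(angles):
            rad = math.radians(ang)
            direction = np.array([math.sin(rad), -math.cos(rad), 0.0])
            sec_id = f"basal_{i:02d}"
            sections[sec_id] = Section(
                id=sec_id,
                category="basal",
                points=_section_points(
                    base, direction, params.basal_length, params.basal_diameter,
                    params.basal_diameter * 0.8,
                ),
                parent=("soma", 0.0),
            )

    return Morphology(sections=sections, root="soma")


# ---------------------------------------------------------------------------
# distances and arbor metrics
# ---------------------------------------------------------------------------

def _section_start_distance(morph: Morphology, section_id: str) -> float:
    """Path distance from the soma centre to the start of a section."""
    sec = morph.sections[section_id]
    if sec.category == "soma":
        return 0.0
    dist = 0.0
    while sec.parent is not None:
        pid, frac = sec.parent
        parent = morph.sections[pid]
        if parent.category == "soma":
            # soma is treated as an isopotential point: distance starts at its centre
            return dist
        dist += frac * parent.length
        sec = parent
    return dist


def path_distance(morph: Morphology, location: tuple[str, float]) -> float:
    """Arc length (µm) along the tree from the soma centre to a location.

    ``location`` is ``(section_id, fraction)`` with fraction in [0, 1] along
    the section's arc.  Locations on the soma itself are at distance 0.
    """
    sec_id, frac = location
    if sec_id not in morph.sections:
        raise KeyError(f"unknown section {sec_id!r}")
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"fraction {frac} outside [0, 1]")
    sec = morph.sections[sec_id]
    if sec.category == "soma":
        return 0.0
    return _section_start_distance(morph, sec_id) + frac * sec.length


def sholl(morph: Morphology, ring_spacing: float) -> ShollProfile:
    """Classical Sholl profile: dendrite crossings of concentric spheres.

    Spheres are centred on the soma centre and spaced ``ring_spacing`` µm
    apart in *Euclidean* radius, out to just beyond the maximal dendritic
    extent.  Each consecutive sample-point pair of each non-soma section that
    straddles a sphere counts one crossing of it.
    """
    if ring_spacing <= 0:
        raise ValueError(f"ring_spacing must be > 0, got {ring_spacing}")
    center = morph.soma_center()
    seg_r = []  # (r_lo, r_hi) per point-pair
    max_r = 0.0
    for sec in morph.sections.values():
        if sec.category == "soma":
            continue
        pts = np.array([[p.x, p.y, p.z] for p in sec.points])
        rr = np.linalg.norm(pts - center, axis=1)
        max_r = max(max_r, float(rr.max()))
        for a, b in zip(rr[:-1], rr[1:]):
            seg_r.append((min(a, b), max(a, b)))
    radii = [ring_spacing * k for k in range(1, int(max_r / ring_spacing) + 2)]
    counts = [sum(1 for lo, hi in seg_r if lo < r <= hi) for r in radii]
    return ShollProfile(radii=radii, intersections=counts)


def branches_at_distance(
    morph: Morphology, distance: float
) -> list[tuple[str, float]]:
    """Locations, one per distinct dendritic route, at a given path distance.

    For every section whose path-distance interval contains ``distance``, the
    ``(section_id, fraction)`` location at exactly that distance is returned,
    restricted to apical sections.  Ordering is deterministic (by section id).
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    out = []
    for sec_id in sorted(morph.sections):
        sec = morph.sections[sec_id]
        if sec.category not in APICAL_CATEGORIES:
            continue
        start = _section_start_distance(morph, sec_id)
        end = start + sec.length
        if start <= distance < end and sec.length > 0:
            out.append((sec_id, (distance - start) / sec.length))
    return out


# ---------------------------------------------------------------------------
# SWC interchange
# ---------------------------------------------------------------------------

def write_swc(
    morph: Morphology,
    sink: Union[str, Path, io.TextIOBase],
    sidecar: Optional[Union[str, Path]] = None,
) -> None:
    """Write standard 7-column SWC.

    Categories map to SWC type codes soma=1, basal=3, apical(any)=4; the
    fine-grained category of each section is preserved in an optional JSON
    sidecar mapping sample index -> category.
    """
    lines = ["# index type x y z radius parent"]
    annot: dict[str, str] = {}
    index_of: dict[tuple[str, int], int] = {}
    nxt = 1
    for sec in morph.ordered_sections():
        code = _CATEGORY_TO_SWC[sec.category]
        for i, p in enumerate(sec.points):
            if i == 0 and sec.parent is not None:
                pid, frac = sec.parent
                parent_sec = morph.sections[pid]
                # attach to the nearest sample of the parent section
                arcs = parent_sec.arc_lengths()
                j = int(np.argmin(np.abs(arcs - frac * arcs[-1])))
                parent_idx = index_of[(pid, j)]
                # skip duplicating the attachment point if coincident
                pp = parent_sec.points[j]
                if (pp.x, pp.y, pp.z) == (p.x, p.y, p.z):
                    index_of[(sec.id, i)] = parent_idx
                    continue
            else:
                parent_idx = index_of[(sec.id, i - 1)] if i > 0 else -1
            idx = nxt
            nxt += 1
            index_of[(sec.id, i)] = idx
            annot[str(idx)] = sec.category
            # repr gives the shortest decimal that round-trips the float exactly
            lines.append(
                f"{idx} {code} {p.x!r} {p.y!r} {p.z!r} {p.diameter / 2!r} {parent_idx}"
            )
    text = "\n".join(lines) + "\n"
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text)
    else:
        sink.write(text)
    if sidecar is not None:
        Path(sidecar).write_text(json.dumps(annot, indent=0))


def read_swc(
    source: Union[str, Path, io.TextIOBase],
    sidecar: Optional[Union[str, Path]] = None,
) -> Morphology:
    """Read a 7-column SWC file into a :class:`Morphology`.

    Unbranched runs of samples with the same type code become one section.
    Type codes map to categories soma=1, basal=3, apical=4 (2, axon, is also
    accepted and treated as apical trunk for robustness); a JSON sidecar
    written by :func:`write_swc` restores fine-grained apical categories.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    annot = {}
    if sidecar is not None:
        annot = json.loads(Path(sidecar).read_text())

    samples: dict[int, tuple[int, float, float, float, float, int]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCParseError(f"expected 7 columns, got {len(parts)}", lineno)
        try:
            idx = int(parts[0])
            code = int(parts[1])
            x, y, z, radius = (float(v) for v in parts[2:6])
            parent = int(parts[6])
        except ValueError as e:
            raise SWCParseError(str(e), lineno) from None
        if idx in samples:
            raise SWCParseError(f"duplicate sample index {idx}", lineno)
        samples[idx] = (code, x, y, z, radius, parent)
    if not samples:
        raise SWCParseError("no samples", 0)
    for idx, (_, _, _, _, _, parent) in samples.items():
        if parent != -1 and parent not in samples:
            raise MorphologyError(f"sample {idx}: parent {parent} does not exist")

    children: dict[int, list[int]] = {}
    roots = []
    for idx in sorted(samples):
        parent = samples[idx][5]
        if parent == -1:
            roots.append(idx)
        else:
            children.setdefault(parent, []).append(idx)
    if len(roots) != 1:
        raise MorphologyError(f"expected exactly one root sample, found {len(roots)}")
    root = roots[0]

    def pt(idx: int) -> Point3D:
        code, x, y, z, r, _ = samples[idx]
        return Point3D(x, y, z, 2 * r)

    # soma: the maximal connected run of type-1 samples containing the root
    soma_idx = [root]
    frontier = [root]
    while frontier:
        cur = frontier.pop()
        for ch in children.get(cur, []):
            if samples[ch][0] == 1:
                soma_idx.append(ch)
                frontier.append(ch)
    soma_pts = [pt(i) for i in soma_idx]
    sections: dict[str, Section] = {
        "soma": Section(id="soma", category="soma", points=soma_pts)
    }
    sample_section: dict[int, str] = {i: "soma" for i in soma_idx}

    counter = [0]

    def build(start: int, parent_section: str):
        """Consume an unbranched run beginning at non-soma sample `start`."""
        code = samples[start][0]
        cat = annot.get(str(start)) or _SWC_TO_CATEGORY.get(code, "apical_trunk")
        parent_sample = samples[start][5]
        run = [pt(parent_sample), pt(start)] if parent_sample != -1 else [pt(start)]
        def cat_of(i: int) -> str:
            return annot.get(str(i)) or _SWC_TO_CATEGORY.get(samples[i][0], "apical_trunk")

        cur = start
        while True:
            ch = children.get(cur, [])
            same = [c for c in ch if samples[c][0] != 1 and cat_of(c) == cat]
            if len(same) == 1 and len(ch) == 1:
                cur = same[0]
                run.append(pt(cur))
            else:
                break
        sec_id = f"{cat}_{counter[0]:03d}"
        counter[0] += 1
        sections[sec_id] = Section(
            id=sec_id, category=cat, points=run, parent=(parent_section, 1.0)
        )
        sample_section[cur] = sec_id
        for c in children.get(cur, []):
            build(c, sec_id)

    for i in soma_idx:
        for ch in children.get(i, []):
            if samples[ch][0] != 1:
                # attachment fraction onto soma is immaterial (isopotential)
                build(ch, "soma")

    morph = Morphology(sections=sections, root="soma")
    return morph
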