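"""Labeled bifurcating airway trees.

The airway domain is a rooted binary tree of straight cylindrical segments:
a single extrathoracic segment (mouth + upper airway, generation -1), the
trachea (generation 0), the two main bronchi (generation 1, together with
the trachea forming the *central* zone), and regular dichotomous branching
below, labeled *distal* down to a diameter cutoff that marks the limit of
what a CT scan can resolve.  Terminal branches are the resolved outlets;
aerosol crossing them is scored as *peripheral* dose of the owning lobe.

The five lobes (RUL, RML, RLL, LUL, LLL) are attached below the main
bronchi: the right main bronchus splits into the RUL bronchus and the
bronchus intermedius, which in turn splits into RML and RLL; the left main
bronchus splits into LUL and LLL.

Every branch carries a 3D frame (origin, axial direction, two transverse
unit vectors) so deposition sites can be mapped to spatial coordinates for
scintigraphy-like projection images.  The frame layout is a deterministic
function of topology and segment lengths and is recomputed after
deserialization rather than stored.
"""

from __future__ import annotations

import csv
import enum
import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Lobe",
    "Zone",
    "Branch",
    "AirwayTree",
    "TreeParams",
    "generate_airway_tree",
    "save_tree",
    "load_tree",
]


class Lobe(str, enum.Enum):
    """The five anatomical lung lobes. RML exists only on the right side."""

    RUL = "RUL"
    RML = "RML"
    RLL = "RLL"
    LUL = "LUL"
    LLL = "LLL"


#: Canonical reporting order of the lobes.
LOBES: tuple[Lobe, ...] = (Lobe.RUL, Lobe.RML, Lobe.RLL, Lobe.LUL, Lobe.LLL)


class Zone(str, enum.Enum):
    """Deposition zones.

    Branches are labeled extrathoracic, central or distal; ``peripheral``
    is an event class (escape through a resolved outlet), not a branch
    label.
    """

    EXTRATHORACIC = "extrathoracic"
    CENTRAL = "central"
    DISTAL = "distal"
    PERIPHERAL = "peripheral"


@dataclass
class Branch:
    """One straight cylindrical airway segment.

    Lengths and radii are in metres.  ``generation`` counts from the
    trachea (0); the extrathoracic segment uses -1.  ``lobe`` is ``None``
    for the extrathoracic segment, trachea, main bronchi and the bronchus
    intermedius (airways serving more than one lobe).
    """

    id: str
    parent: str | None
    children: list[str]
    generation: int
    length: float
    radius: float
    lobe: Lobe | None
    zone: Zone
    # 3D frame, filled in by assign_frames()
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -1.0]))
    e1: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    e2: np.ndarray = field(default_factory=lambda: np.array([0.0, -1.0, 0.0]))

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"branch {self.id}: radius must be > 0")
        if self.length <= 0:
            raise ValueError(f"branch {self.id}: length must be > 0")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def is_terminal(self) -> bool:
        return not self.children

    @property
    def outlet_area(self) -> float:
        """Outlet cross-section area (terminal branches only), m^2."""
        if not self.is_terminal:
            raise ValueError(f"branch {self.id} is not terminal")
        return math.pi * self.radius**2


class TreeArrays:
    """Flat array view of an :class:`AirwayTree` for vectorised kernels.

    Branches are indexed in breadth-first order from the root; ``-1``
    encodes a missing parent/child.
    """

    def __init__(self, tree: "AirwayTree") -> None:
        order: list[str] = []
        queue = [tree.root]
        while queue:
            bid = queue.pop(0)
            order.append(bid)
            queue.extend(sorted(tree[bid].children))
        self.ids: list[str] = order
        self.index: dict[str, int] = {bid: i for i, bid in enumerate(order)}
        n = len(order)
        self.parent = np.full(n, -1, dtype=np.int64)
        self.child1 = np.full(n, -1, dtype=np.int64)
        self.child2 = np.full(n, -1, dtype=np.int64)
        self.length = np.empty(n)
        self.radius = np.empty(n)
        self.generation = np.empty(n, dtype=np.int64)
        self.zone = np.empty(n, dtype=np.int64)  # 0 ET, 1 central, 2 distal
        self.lobe = np.full(n, -1, dtype=np.int64)  # index into LOBES, -1 none
        self.is_terminal = np.zeros(n, dtype=bool)
        self.origin = np.empty((n, 3))
        self.direction = np.empty((n, 3))
        self.e1 = np.empty((n, 3))
        self.e2 = np.empty((n, 3))
        zcode = {Zone.EXTRATHORACIC: 0, Zone.CENTRAL: 1, Zone.DISTAL: 2}
        lcode = {lb: i for i, lb in enumerate(LOBES)}
        for i, bid in enumerate(order):
            br = tree[bid]
            if br.parent is not None:
                self.parent[i] = self.index[br.parent]
            kids = sorted(br.children)
            if kids:
                self.child1[i] = self.index[kids[0]]
            if len(kids) > 1:
                self.child2[i] = self.index[kids[1]]
            self.length[i] = br.length
            self.radius[i] = br.radius
            self.generation[i] = br.generation
            self.zone[i] = zcode[br.zone]
            if br.lobe is not None:
                self.lobe[i] = lcode[br.lobe]
            self.is_terminal[i] = br.is_terminal
            self.origin[i] = br.origin
            self.direction[i] = br.direction
            self.e1[i] = br.e1
            self.e2[i] = br.e2
        self.root = 0


@dataclass
class AirwayTree:
    """A labeled bifurcating airway geometry."""

    branches: dict[str, Branch]
    root: str
    diameter_cutoff: float

    def __getitem__(self, bid: str) -> Branch:
        return self.branches[bid]

    def __iter__(self):
        return iter(self.branches.values())

    def __len__(self) -> int:
        return len(self.branches)

    def terminals(self) -> list[Branch]:
        return [b for b in self.branches.values() if b.is_terminal]

    def lobes_present(self) -> set[Lobe]:
        return {b.lobe for b in self.branches.values() if b.lobe is not None}

    def total_volume(self) -> float:
        """Total airway lumen volume, m^3."""
        return sum(math.pi * b.radius**2 * b.length for b in self.branches.values())

    _arrays_cache: TreeArrays | None = field(default=None, repr=False, compare=False)

    def arrays(self) -> TreeArrays:
        if self._arrays_cache is None:
            self._arrays_cache = TreeArrays(self)
        return self._arrays_cache

    def validate(self) -> None:
        """Check connectivity, acyclicity and label consistency."""
        seen: set[str] = set()
        queue = [self.root]
        while queue:
            bid = queue.pop()
            if bid in seen:
                raise ValueError("cycle detected in airway tree")
            seen.add(bid)
            queue.extend(self[bid].children)
        if seen != set(self.branches):
            raise ValueError("airway tree is not connected from the root")
        for br in self:
            for cid in br.children:
                child = self[cid]
                if br.lobe is not None and child.lobe != br.lobe:
                    raise ValueError(
                        f"lobe label of {cid} inconsistent with parent {br.id}"
                    )


@dataclass(frozen=True)
class TreeParams:
    """Geometric parameters of the synthetic airway tree.

    Defaults give a symmetric dichotomous tree with an 18 mm diameter, 10 cm
    long trachea, per-generation diameter ratio 0.75 and length ratio 0.62
    (the fast taper of real conducting airways), and a 1.5 mm diameter
    cutoff separating CT-resolvable (distal) airways from the unresolved
    periphery.  These defaults terminate at generation 9 (512 outlets)
    with ~145 mL of airway dead space, in the anatomical range; the
    classical volume-preserving ratio 2^(-1/3) is available but reaches the
    cutoff only at generation 11 with a dead space comparable to a resting
    tidal volume, which suppresses outlet escape.
    """

    trachea_radius: float = 0.009
    trachea_length: float = 0.10
    diameter_ratio: float = 0.75
    length_ratio: float = 0.62
    diameter_cutoff: float = 0.0015
    extrathoracic_length: float = 0.20
    extrathoracic_radius: float = 0.010
    max_generations: int = 16
    branching_angle_deg: float = 35.0


# naming scheme: extrathoracic "mouth"; trachea "T"; main bronchi "R"/"L";
# below a lobar root, children append "0"/"1" to the parent id.
_LOBE_ROOTS = {"R0": Lobe.RUL, "R10": Lobe.RML, "R11": Lobe.RLL,
               "L0": Lobe.LUL, "L1": Lobe.LLL}


def generate_airway_tree(params: TreeParams | None = None, seed: int = 0) -> AirwayTree:
    """Generate a symmetric dichotomous airway tree.

    The structure is fully determined by ``params``; ``seed`` is accepted
    for interface uniformity with the other generators and does not alter
    the geometry (generation is deterministic by construction).

    Raises
    ------
    ValueError
        If ``diameter_ratio`` is not in (0, 1), or the parameter set
        produces no lobar branches (e.g. a cutoff wider than the trachea).
    """
    p = params or TreeParams()
    if not (0.0 < p.diameter_ratio < 1.0):
        raise ValueError("diameter_ratio must be in (0, 1)")
    if p.diameter_cutoff >= 2.0 * p.trachea_radius:
        # still build what exists (mouth + trachea) to give a precise error
        pass

    branches: dict[str, Branch] = {}

    def add(bid, parent, gen, length, radius, lobe, zone):
        branches[bid] = Branch(bid, parent, [], gen, length, radius, lobe, zone)
        if parent is not None:
            branches[parent].children.append(bid)

    add("mouth", None, -1, p.extrathoracic_length, p.extrathoracic_radius,
        None, Zone.EXTRATHORACIC)
    add("T", "mouth", 0, p.trachea_length, p.trachea_radius, None, Zone.CENTRAL)

    # grow generation by generation; a branch gets children while its
    # diameter is >= cutoff and the generation cap is not reached
    frontier = ["T"]
    while frontier:
        nxt: list[str] = []
        for bid in frontier:
            br = branches[bid]
            if br.diameter < p.diameter_cutoff or br.generation >= p.max_generations:
                continue
            radius = br.radius * p.diameter_ratio
            length = br.length * p.length_ratio
            gen = br.generation + 1
            if bid == "T":
                kids = ["L", "R"]
            else:
                kids = [bid + "0", bid + "1"]
            for kid in kids:
                lobe = _LOBE_ROOTS.get(kid, br.lobe)
                zone = Zone.CENTRAL if gen <= 1 else Zone.DISTAL
                add(kid, bid, gen, length, radius, lobe, zone)
                nxt.append(kid)
        frontier = nxt

    tree = AirwayTree(branches=branches, root="mouth",
                      diameter_cutoff=p.diameter_cutoff)
    missing = set(LOBES) - tree.lobes_present()
    if missing:
        names = ", ".join(sorted(l.value for l in missing))
        raise ValueError(f"no lobar branches for: {names}")
    assign_frames(tree, branching_angle_deg=p.branching_angle_deg)
    tree.validate()
    return tree


def assign_frames(tree: AirwayTree, branching_angle_deg: float = 35.0) -> None:
    """Assign 3D frames (origin, direction, transverse basis) to all branches.

    Deterministic layout: the extrathoracic segment and trachea point along
    -z; at each bifurcation the children directions are the parent
    direction rotated by +/- the branching angle, in a plane that
    alternates with generation parity so the tree spreads in 3D.  Children
    are ordered alphabetically by id (fixed tie-break).
    """
    theta = math.radians(branching_angle_deg)
    root = tree[tree.root]
    root.origin = np.zeros(3)
    root.direction = np.array([0.0, 0.0, -1.0])
    root.e1 = np.array([1.0, 0.0, 0.0])
    root.e2 = np.cross(root.direction, root.e1)
    queue = [tree.root]
    while queue:
        bid = queue.pop(0)
        br = tree[bid]
        end = br.origin + br.length * br.direction
        kids = sorted(br.children)
        # rotation plane axis alternates with generation parity
        axis = br.e1 if (br.generation % 2 == 0) else br.e2
        for i, cid in enumerate(kids):
            child = tree[cid]
            child.origin = end
            if len(kids) == 1:
                d = br.direction.copy()
            else:
                sign = -1.0 if i == 0 else 1.0
                d = math.cos(theta) * br.direction + sign * math.sin(theta) * axis
                d /= np.linalg.norm(d)
            child.direction = d
            # transverse frame: e1 orthogonal to d, seeded from parent e1
            seed_vec = br.e1 if abs(np.dot(br.e1, d)) < 0.9 else br.e2
            e1 = seed_vec - np.dot(seed_vec, d) * d
            e1 /= np.linalg.norm(e1)
            child.e1 = e1
            child.e2 = np.cross(d, e1)
            queue.append(cid)


_COLUMNS = ["id", "parent", "generation", "length_m", "radius_m", "lobe", "zone"]


def tree_to_text(tree: AirwayTree) -> str:
    """Serialize a tree to delimited text, one branch per record."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(_COLUMNS)
    arrays = tree.arrays()
    for bid in arrays.ids:  # stable BFS order -> bytewise reproducible
        b = tree[bid]
        w.writerow([
            b.id,
            b.parent if b.parent is not None else "",
            b.generation,
            repr(b.length),
            repr(b.radius),
            b.lobe.value if b.lobe is not None else "",
            b.zone.value,
        ])
    return buf.getvalue()


def tree_from_text(text: str, diameter_cutoff: float = 0.0015,
                   branching_angle_deg: float = 35.0) -> AirwayTree:
    rows = list(csv.DictReader(io.StringIO(text)))
    branches: dict[str, Branch] = {}
    root = None
    for r in rows:
        parent = r["parent"] or None
        lobe = Lobe(r["lobe"]) if r["lobe"] else None
        branches[r["id"]] = Branch(
            r["id"], parent, [], int(r["generation"]),
            float(r["length_m"]), float(r["radius_m"]), lobe, Zone(r["zone"]),
        )
        if parent is None:
            root = r["id"]
    if root is None:
        raise ValueError("serialized tree has no root")
    for b in branches.values():
        if b.parent is not None:
            branches[b.parent].children.append(b.id)
    tree = AirwayTree(branches=branches, root=root, diameter_cutoff=diameter_cutoff)
    assign_frames(tree, branching_angle_deg=branching_angle_deg)
    tree.validate()
    return tree


def save_tree(tree: AirwayTree, path: str | Path) -> None:
    Path(path).write_text(tree_to_text(tree))


def load_tree(path: str | Path, diameter_cutoff: float = 0.0015) -> AirwayTree:
    return tree_from_text(Path(path).read_text(), diameter_cutoff=diameter_cutoff)
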