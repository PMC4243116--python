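"""Synthetic protein families with planted, co-occurring motifs.

The generator emulates the kind of input the pipeline is designed for: a
family of homologous sequences in which a handful of conserved motifs are
present on overlapping subsets of sequences.  Motif presence follows a
configurable co-occurrence design: motifs in a *joint group* appear together
(the whole group is present with one probability per sequence), while
*independent* motifs are drawn per sequence on their own.  Present motifs
are implanted over background residues (no net length change unless an
indel rate is set) with independent per-position substitutions.

A paired synthetic "structure" provides a Calpha trace with exact 3.8 A
consecutive spacing in which the planted motif regions are either folded
close together ("colocated") or pushed far apart ("dispersed"), so the 3D
validation stage can be exercised without any downloaded structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .apc import AlignedPatternCluster
from .io_seq import AMINO_ACIDS, SequenceRecord, SequenceSet
from .structure3d import ResidueCA, StructureModel

CA_SPACING = 3.8  # Angstrom between consecutive Calpha atoms

_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


@dataclass(frozen=True)
class Motif:
    """A planted motif: consensus string, substitution rate, implant site."""

    consensus: str
    mutation_rate: float = 0.0
    site: int | None = None  # 0-based implant start; None -> even layout


@dataclass(frozen=True)
class JointGroup:
    """Indices of motifs implanted together, with the group's presence
    probability per sequence."""

    motifs: tuple[int, ...]
    probability: float


@dataclass
class SyntheticSpec:
    """Full description of a synthetic family.

    Every motif index must appear either in exactly one joint group or in
    ``independent_probs``.  With a fixed seed the emitted family (and any
    structure derived from its truth) is byte-identical across runs.
    """

    motifs: list[Motif]
    n_sequences: int = 100
    length: int = 150
    joint_groups: list[JointGroup] = field(default_factory=list)
    independent_probs: dict[int, float] = field(default_factory=dict)
    background: dict[str, float] | None = None  # None -> uniform over the 20 letters
    indel_rate: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        grouped = [i for g in self.joint_groups for i in g.motifs]
        declared = sorted(grouped + list(self.independent_probs))
        if declared != list(range(len(self.motifs))):
            raise ValueError(
                "every motif index must appear in exactly one joint group or "
                "in independent_probs"
            )
        for g in self.joint_groups:
            if not 0.0 <= g.probability <= 1.0:
                raise ValueError("group probability outside [0, 1]")
        for p in self.independent_probs.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("independent probability outside [0, 1]")
        for m in self.motifs:
            if len(m.consensus) >= self.length:
                raise ValueError("motif longer than the sequence length")
        sites = self.sites()
        spans = sorted((s, s + len(self.motifs[i].consensus))
                       for i, s in enumerate(sites))
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            if lo2 < hi1:
                raise ValueError("motifs overlap at their implant sites")
        if spans and spans[-1][1] > self.length:
            raise ValueError("motif extends past the sequence end")

    def sites(self) -> list[int]:
        """Implant site of each motif (auto-layout spreads them evenly)."""
        out = []
        n = len(self.motifs)
        for i, m in enumerate(self.motifs):
            if m.site is not None:
                out.append(m.site)
            else:
                block = self.length // n
                out.append(i * block + (block - len(m.consensus)) // 2)
        return out

    def group_of(self) -> dict[int, str]:
        labels: dict[int, str] = {}
        for gi, g in enumerate(self.joint_groups):
            for i in g.motifs:
                labels[i] = f"joint{gi + 1}"
        for i in self.independent_probs:
            labels[i] = f"indep{i}"
        return labels


@dataclass
class SyntheticTruth:
    """Ground truth of a generated family.

    ``presence[seq_id]`` maps motif index -> 0-based implant position for the
    motifs planted in that sequence; ``group_of`` records the expected
    co-occurrence group label of each motif.
    """

    consensi: list[str]
    presence: dict[str, dict[int, int]]
    group_of: dict[int, str]

    def support_set(self, motif: int) -> frozenset[str]:
        return frozenset(sid for sid, got in self.presence.items() if motif in got)

    def jaccard(self, i: int, j: int) -> float:
        a, b = self.support_set(i), self.support_set(j)
        union = a | b
        return len(a & b) / len(union) if union else 0.0


def generate_family(spec: SyntheticSpec) -> tuple[SequenceSet, SyntheticTruth]:
    """Draw a synthetic family and its ground truth from the spec."""
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(AMINO_ACIDS))
    if spec.background is None:
        probs = np.full(len(letters), 1.0 / len(letters))
    else:
        probs = np.array([spec.background.get(aa, 0.0) for aa in AMINO_ACIDS])
        probs = probs / probs.sum()
    sites = spec.sites()

    records: list[SequenceRecord] = []
    presence: dict[str, dict[int, int]] = {}
    width = max(3, len(str(spec.n_sequences)))
    for si in range(spec.n_sequences):
        sid = f"seq{si + 1:0{width}d}"
        residues = list(rng.choice(letters, size=spec.length, p=probs))
        planted: dict[int, int] = {}
        for g in spec.joint_groups:
            if rng.random() < g.probability:
                for mi in g.motifs:
                    planted[mi] = sites[mi]
        for mi, p in spec.independent_probs.items():
            if rng.random() < p:
                planted[mi] = sites[mi]
        for mi in sorted(planted):
            m = spec.motifs[mi]
            start = planted[mi]
            for off, ch in enumerate(m.consensus):
                if m.mutation_rate > 0 and rng.random() < m.mutation_rate:
                    alternatives = [a for a in AMINO_ACIDS if a != ch]
                    residues[start + off] = alternatives[rng.integers(len(alternatives))]
                else:
                    residues[start + off] = ch
        if spec.indel_rate > 0:
            residues, planted = _apply_indels(
                residues, planted, spec, sites, rng, letters, probs
            )
        records.append(SequenceRecord(id=sid, residues="".join(residues)))
        presence[sid] = planted
    truth = SyntheticTruth(
        consensi=[m.consensus for m in spec.motifs],
        presence=presence,
        group_of=spec.group_of(),
    )
    return SequenceSet(records), truth


def _apply_indels(residues, planted, spec, sites, rng, letters, probs):
    """Insertions/deletions restricted to background positions, so planted
    motif copies stay intact and their recorded positions stay exact."""
    motif_positions = set()
    for mi, start in planted.items():
        motif_positions.update(range(start, start + len(spec.motifs[mi].consensus)))
    out: list[str] = []
    new_planted = dict.fromkeys(planted, -1)
    for pos, ch in enumerate(residues):
        for mi, start in planted.items():
            if pos == start:
                new_planted[mi] = len(out)
        if pos in motif_positions:
            out.append(ch)
            continue
        r = rng.random()
        if r < spec.indel_rate / 2:
            continue  # deletion
        out.append(ch)
        if r > 1 - spec.indel_rate / 2:
            out.append(str(rng.choice(letters, p=probs)))  # insertion
    return out, new_planted


# ---------------------------------------------------------------------------
# Synthetic Calpha structure
# ---------------------------------------------------------------------------

def generate_structure_for(truth: SyntheticTruth, record: SequenceRecord,
                           geometry: str = "colocated") -> StructureModel:
    """Synthetic Calpha trace for one family member.

    Consecutive Calpha atoms are exactly 3.8 A apart.  The chain follows a
    helical "pursuit" path around a moving center: during a planted motif
    region the center is pinned at that motif's anchor point, so the region
    coils into a compact ball around the anchor; linkers take an excursion
    between anchors so that the chain as a whole has real spatial extent.

    geometry="colocated" places all anchors within a small ball (motif
    centroids end up well inside 15 A of one another); "dispersed" spreads
    anchors 60 A apart along x (centroid separations at least 40 A).
    """
    if geometry not in ("colocated", "dispersed"):
        raise ValueError("geometry must be 'colocated' or 'dispersed'")
    if record.id not in truth.presence:
        raise ValueError(f"{record.id!r} is not a member of this family")
    planted = truth.presence[record.id]
    length = len(record.residues)
    order = sorted(planted, key=lambda mi: planted[mi])

    anchors: dict[int, np.ndarray] = {}
    for rank, mi in enumerate(order):
        if geometry == "colocated":
            angle = 2 * math.pi * rank / max(1, len(order))
            anchors[mi] = 3.0 * np.array([math.cos(angle), math.sin(angle), 0.0])
        else:
            anchors[mi] = np.array([60.0 * rank, 0.0, 0.0])

    centers = _center_path(length, planted, truth, order, anchors)

    radius, omega = 4.0, 0.7
    positions = np.zeros((length, 3))
    positions[0] = centers[0] + np.array([radius, 0.0, 0.0])
    for i in range(1, length):
        target = centers[i] + radius * np.array(
            [math.cos(omega * i), math.sin(omega * i), 0.15 * math.sin(0.37 * i)]
        )
        step = target - positions[i - 1]
        norm = np.linalg.norm(step)
        if norm < 1e-9:
            step, norm = np.array([1.0, 0.0, 0.0]), 1.0
        positions[i] = positions[i - 1] + CA_SPACING * step / norm

    residues = [
        ResidueCA(
            name=_THREE_LETTER[ch],
            number=i + 1,
            one_letter=ch,
            coord=(float(x), float(y), float(z)),
        )
        for i, (ch, (x, y, z)) in enumerate(zip(record.residues, positions))
    ]
    return StructureModel(source_id=f"synthetic-{record.id}-{geometry}",
                          chains={"A": residues})


def _center_path(length, planted, truth, order, anchors) -> np.ndarray:
    """Per-residue center: pinned at anchors inside motifs, linear with an
    out-and-back excursion across linkers."""
    centers = np.zeros((length, 3))
    spans = [(planted[mi], planted[mi] + len(truth.consensi[mi]), anchors[mi])
             for mi in order]
    waypoints: list[tuple[int, np.ndarray]] = []
    excursion = np.array([0.0, 0.0, 25.0])
    prev_end = 0
    prev_anchor = (spans[0][2] + excursion) if spans else np.zeros(3)
    for k, (lo, hi, anchor) in enumerate(spans):
        if lo > prev_end:
            mid = (prev_end + lo) // 2
            bump = excursion if k % 2 == 0 else -excursion
            waypoints.append((mid, (prev_anchor + anchor) / 2 + bump))
        waypoints.append((lo, anchor))
        waypoints.append((hi - 1, anchor))
        prev_end = hi
        prev_anchor = anchor
    if prev_end < length:
        waypoints.append((length - 1, prev_anchor + excursion))
    if not waypoints:
        waypoints = [(0, np.zeros(3)), (length - 1, np.array([0.0, 0.0, 25.0]))]
    if waypoints[0][0] > 0:
        waypoints.insert(0, (0, waypoints[0][1]))

    idx = np.array([w[0] for w in waypoints])
    pts = np.array([w[1] for w in waypoints])
    for d in range(3):
        centers[:, d] = np.interp(np.arange(length), idx, pts[:, d])
    return centers


# ---------------------------------------------------------------------------
# Truth-based evaluation helpers
# ---------------------------------------------------------------------------

def match_apcs_to_motifs(apcs: list[AlignedPatternCluster],
                         truth: SyntheticTruth) -> dict[str, int | None]:
    """Assign each APC to the planted motif its occurrences overlap most.

    Overlap is counted position-wise between member-pattern occurrences and
    the true implanted spans; an APC with no overlap maps to None.
    """
    out: dict[str, int | None] = {}
    for c in apcs:
        overlap: dict[int, int] = {}
        for m in c.members:
            n = len(m.symbols)
            for sid, start in m.occurrences:
                for mi, mstart in truth.presence.get(sid, {}).items():
                    mend = mstart + len(truth.consensi[mi])
                    ov = min(start + n, mend) - max(start, mstart)
                    if ov > 0:
                        overlap[mi] = overlap.get(mi, 0) + ov
        if overlap:
            best = max(overlap.values())
            out[c.id] = min(mi for mi, v in overlap.items() if v == best)
        else:
            out[c.id] = None
    return out
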