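"""Mapping APCs onto a reference 3D structure and distance validation.

Conserved regions that co-occur on sequences are expected to sit close
together in the folded protein.  This module parses a PDB structure (first
model, Calpha atoms), locates each APC's patterns on a chain sequence,
averages the Calpha positions of each matched region into a centroid, and
compares the mean inter-centroid distance with the structure-wide baseline:
the mean Euclidean distance over all unordered Calpha pairs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.distance import pdist

from .apc import AlignedPatternCluster
from .io_seq import GAP, WILDCARD


@dataclass(frozen=True)
class ResidueCA:
    """One residue reduced to its Calpha representative."""

    name: str          # three-letter residue name
    number: int        # author residue number
    one_letter: str    # derived one-letter code (X for non-standard)
    coord: tuple[float, float, float]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord)


@dataclass
class StructureModel:
    """First model of a structure: per chain, ordered Calpha residues."""

    source_id: str
    chains: dict[str, list[ResidueCA]]

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chains[chain_id])

    def ca_coords(self, chains: list[str] | None = None) -> np.ndarray:
        chain_ids = chains if chains is not None else list(self.chains)
        coords = [r.xyz for cid in chain_ids for r in self.chains[cid]]
        return np.asarray(coords)

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())


def read_structure(path: str | Path) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Uses the first model only; hetero compounds and waters are excluded;
    residues lacking a Calpha are skipped with a warning; for altloc
    Calphas the highest-occupancy location is kept.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    chains: dict[str, list[ResidueCA]] = {}
    skipped = 0
    for chain in model:
        residues: list[ResidueCA] = []
        for res in chain:
            if res.is_water() or res.het_flag == "H":
                continue
            cas = [a for a in res if a.name == "CA" and a.element.name == "C"]
            if not cas:
                skipped += 1
                continue
            ca = max(cas, key=lambda a: a.occ)
            info = gemmi.find_tabulated_residue(res.name)
            one = info.one_letter_code.upper() if info else "X"
            if not one.isalpha():
                one = "X"
            residues.append(ResidueCA(
                name=res.name,
                number=res.seqid.num,
                one_letter=one,
                coord=(ca.pos.x, ca.pos.y, ca.pos.z),
            ))
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise ValueError(f"no Calpha atoms in {path}")
    if skipped:
        warnings.warn(f"{skipped} residue(s) without Calpha skipped")
    return StructureModel(source_id=st.name or Path(path).stem, chains=chains)


def write_ca_pdb(s: StructureModel, path: str | Path) -> None:
    """Write a Calpha-only PDB file (one ATOM record per residue)."""
    lines = []
    serial = 0
    for cid, residues in s.chains.items():
        for r in residues:
            serial += 1
            x, y, z = r.coord
            lines.append(
                f"ATOM  {serial:5d}  CA  {r.name:>3s} {cid[:1]}{r.number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C  "
            )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# APC region mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """A matched stretch on one chain, 0-based half-open residue indices."""

    chain_id: str
    start: int
    end: int

    @property
    def span_1based(self) -> tuple[int, int]:
        return self.start + 1, self.end


def _pattern_regex(symbols: str) -> re.Pattern:
    """Regex for a (possibly wildcarded) pattern; gaps are skipped."""
    parts = []
    for ch in symbols:
        if ch == GAP:
            continue
        parts.append("." if ch == WILDCARD else re.escape(ch))
    return re.compile("(?=(" + "".join(parts) + "))")


def _scan(symbols: str, chain_seq: str) -> list[tuple[int, int]]:
    clean = symbols.replace(GAP, "")
    return [(m.start(), m.start() + len(clean))
            for m in _pattern_regex(symbols).finditer(chain_seq)]


def _partial_matches(symbols: str, chain_seq: str, min_partial: int
                     ) -> list[tuple[int, int]]:
    """Maximal exact sub-matches of length >= min_partial ('parts of the APC')."""
    clean = symbols.replace(GAP, "").replace(WILDCARD, "")
    for length in range(len(clean) - 1, min_partial - 1, -1):
        hits = []
        for off in range(len(clean) - length + 1):
            hits.extend(_scan(clean[off:off + length], chain_seq))
        if hits:
            return hits
    return []


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(spans):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _best_chain(apcs: list[AlignedPatternCluster], s: StructureModel) -> str:
    """Chain with the most full pattern matches (ties: first chain)."""
    best_cid, best_hits = next(iter(s.chains)), -1
    for cid in s.chains:
        seq = s.chain_sequence(cid)
        hits = sum(
            1 for c in apcs for m in c.members if m.symbols in seq
        )
        if hits > best_hits:
            best_cid, best_hits = cid, hits
    return best_cid


def map_apc_to_structure(c: AlignedPatternCluster, s: StructureModel,
                         chain: str | None = None,
                         min_partial: int = 5,
                         wildcard_entropy: float | None = None) -> list[Region]:
    """Locate an APC's patterns on a chain sequence.

    Member patterns are scanned exactly; the consensus (wildcarded at
    columns above ``wildcard_entropy`` bits, when given) is scanned with "*"
    matching any residue.  When no full pattern matches, maximal partial
    matches of at least ``min_partial`` residues are accepted.  Overlapping
    matched spans are merged.  Returns [] when the APC cannot be placed.
    """
    cid = chain if chain is not None else _best_chain([c], s)
    seq = s.chain_sequence(cid)
    spans: list[tuple[int, int]] = []
    for m in c.members:
        spans.extend(_scan(m.symbols, seq))
    spans.extend(_scan(c.consensus(max_column_entropy=wildcard_entropy), seq))
    if not spans:
        for m in c.members:
            spans.extend(_partial_matches(m.symbols, seq, min_partial))
    if not spans:
        warnings.warn(f"APC {c.id} could not be mapped onto chain {cid}")
        return []
    return [Region(chain_id=cid, start=lo, end=hi)
            for lo, hi in _merge_spans(spans)]


def region_centroid(s: StructureModel, region: Region) -> np.ndarray:
    """Arithmetic mean of the Calpha coordinates of a region."""
    residues = s.chains[region.chain_id][region.start:region.end]
    if not residues:
        raise ValueError("empty region")
    return np.mean([r.xyz for r in residues], axis=0)


def average_apc_distance(centroids: list[np.ndarray] | np.ndarray) -> float:
    """Mean Euclidean distance over all unordered centroid pairs (Angstrom)."""
    pts = np.asarray(centroids, dtype=float)
    if len(pts) < 2:
        raise ValueError("need >= 2 mapped APCs")
    return float(pdist(pts).mean())


def average_pairwise_ca_distance(s: StructureModel,
                                 chains: list[str] | None = None) -> float:
    """Mean Euclidean distance over all unordered Calpha pairs (Angstrom).

    By default every chain of the first model contributes, matching a
    baseline computed over the whole deposited structure; pass ``chains`` to
    restrict to a subset.
    """
    coords = s.ca_coords(chains)
    if len(coords) < 2:
        raise ValueError("need >= 2 Calpha atoms")
    return float(pdist(coords).mean())


@dataclass
class StructureMapping:
    """APC -> structure regions with centroid-based distance summaries."""

    structure_id: str
    regions: dict[str, list[Region]]
    chosen_region: dict[str, Region]
    centroids: dict[str, np.ndarray]
    unmapped: list[str] = field(default_factory=list)
    average_apc_dist: float | None = None
    average_pairwise_dist: float | None = None


def map_apcs(apcs: list[AlignedPatternCluster], s: StructureModel,
             chain: str | None = None, min_partial: int = 5,
             wildcard_entropy: float | None = None) -> StructureMapping:
    """Map a set of APCs onto one chain and summarize their 3D closeness.

    The chain defaults to the one with the most full pattern matches.  When
    an APC matches several disjoint regions, the region whose centroid lies
    nearest the mean centroid of the other APCs is kept (alternatives remain
    listed in ``regions``).
    """
    cid = chain if chain is not None else _best_chain(apcs, s)
    regions: dict[str, list[Region]] = {}
    unmapped: list[str] = []
    for c in apcs:
        r = map_apc_to_structure(c, s, chain=cid, min_partial=min_partial,
                                 wildcard_entropy=wildcard_entropy)
        if r:
            regions[c.id] = r
        else:
            unmapped.append(c.id)

    provisional = {
        apc_id: region_centroid(s, rs[0]) for apc_id, rs in regions.items()
    }
    chosen: dict[str, Region] = {}
    centroids: dict[str, np.ndarray] = {}
    for apc_id, rs in regions.items():
        if len(rs) == 1:
            chosen[apc_id] = rs[0]
        else:
            others = [v for k, v in provisional.items() if k != apc_id]
            if others:
                anchor = np.mean(others, axis=0)
                chosen[apc_id] = min(
                    rs, key=lambda r: float(np.linalg.norm(region_centroid(s, r) - anchor))
                )
            else:
                chosen[apc_id] = max(rs, key=lambda r: r.end - r.start)
        centroids[apc_id] = region_centroid(s, chosen[apc_id])

    mapping = StructureMapping(
        structure_id=s.source_id,
        regions=regions,
        chosen_region=chosen,
        centroids=centroids,
        unmapped=unmapped,
    )
    if len(centroids) >= 2:
        mapping.average_apc_dist = average_apc_distance(list(centroids.values()))
    mapping.average_pairwise_dist = average_pairwise_ca_distance(s)
    return mapping
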