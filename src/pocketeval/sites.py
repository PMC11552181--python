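"""Binding-site definition from ligand interaction fingerprints.

The procedure aggregates protein–ligand interfaces across all structures of
one protein in UniProt residue space, which makes it independent of any
structural superposition:

1. each ligand instance contributes a *fingerprint* — the set of UniProt
   residue numbers whose heavy atoms lie within a contact cutoff of any
   ligand heavy atom;
2. instances with identical fingerprints are collapsed into one interface
   group (the protein–ligand interface repeated across copies of an
   assembly, or across structures, counts once);
3. the remaining unique fingerprints are clustered with average-linkage
   hierarchical clustering on the distance D = 1 − I_rel, where the relative
   intersection I_rel(A, B) = |A ∩ B| / min(|A|, |B|);
4. cutting the dendrogram at D = 0.5 yields the binding sites; each site's
   residue set is the union of its member fingerprints.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .errors import InvariantError, UndefinedResultError
from .model import Atom, Chain, Fingerprint, validate_fingerprint

log = logging.getLogger(__name__)

#: Heavy-atom contact cutoff (Å) standing in for an interatomic-contact tool.
DEFAULT_CONTACT_CUTOFF = 4.5
#: Dendrogram cut distance: fingerprints merge while D <= this value.
DEFAULT_CLUSTER_CUT = 0.5


@dataclass
class InterfaceGroup:
    """Ligand instances sharing one identical contact fingerprint."""

    fingerprint: frozenset
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        self.fingerprint = validate_fingerprint(self.fingerprint)
        if not self.members:
            raise InvariantError("interface group must have at least one member")

    @property
    def multiplicity(self) -> int:
        return len(self.members)


@dataclass
class BindingSite:
    """A clustered, non-redundant observed ligand binding site."""

    site_id: str
    residues: frozenset
    members: tuple[str, ...]
    multiplicity: int = 0
    centroid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.residues = frozenset(int(r) for r in self.residues)
        if not self.members:
            raise InvariantError("binding site must have at least one member")
        if self.multiplicity <= 0:
            self.multiplicity = len(self.members)
        if self.centroid is not None:
            self.centroid = np.asarray(self.centroid, dtype=float)


def compute_contacts(
    chain: Chain,
    ligand_atoms: Sequence[Atom],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> frozenset:
    """Fingerprint of a ligand on a chain: residues with any heavy atom
    within ``cutoff`` Å of any ligand heavy atom, in UniProt numbering.

    Raises
    ------
    UndefinedResultError
        If a contacting residue lacks a UniProt mapping — fingerprints must
        be complete in UniProt space, so a partial one is an error rather
        than a silently truncated set.
    """
    lig = np.array([a.coords for a in ligand_atoms if a.is_heavy]).reshape(-1, 3)
    if lig.size == 0:
        raise InvariantError("ligand has no heavy atoms")
    contacts: set[int] = set()
    unmapped: list[str] = []
    for res in chain.residues:
        coords = res.heavy_coords()
        if coords.size == 0:
            continue
        if np.min(cdist(coords, lig)) <= cutoff:
            if res.uniprot_num is None:
                unmapped.append(res.auth_id)
            else:
                contacts.add(res.uniprot_num)
    if unmapped:
        raise UndefinedResultError(
            "contacting residue(s) without UniProt mapping: " + ", ".join(unmapped)
        )
    return frozenset(contacts)


def relative_intersection(a: frozenset, b: frozenset) -> tuple[float, float]:
    """Relative intersection I_rel and distance D = 1 − I_rel.

    I_rel = |A ∩ B| / min(|A|, |B|): the observed intersection relative to
    the maximum attainable one, so I_rel ∈ [0, 1] with I_rel(A, A) = 1.
    """
    a = validate_fingerprint(frozenset(a))
    b = validate_fingerprint(frozenset(b))
    i_rel = len(a & b) / min(len(a), len(b))
    return i_rel, 1.0 - i_rel


def deduplicate_interfaces(
    fingerprints: Sequence[tuple[str, frozenset]],
) -> list[InterfaceGroup]:
    """Collapse ligand instances with identical fingerprints into groups.

    Instances with empty fingerprints are excluded with a warning (the
    clustering distance is undefined for empty sets).
    """
    groups: dict[frozenset, list[str]] = {}
    order: list[frozenset] = []
    for instance_id, fp in fingerprints:
        fp = frozenset(int(r) for r in fp)
        if not fp:
            log.warning("ligand %s has an empty fingerprint; excluded", instance_id)
            continue
        if fp not in groups:
            groups[fp] = []
            order.append(fp)
        groups[fp].append(instance_id)
    return [InterfaceGroup(fingerprint=fp, members=tuple(groups[fp])) for fp in order]


def _sort_key(group: InterfaceGroup):
    # deterministic tie-breaking: order-invariance of the clustering
    fp = tuple(sorted(group.fingerprint))
    return (fp[0], len(fp), fp)


def define_sites(
    groups: Sequence[InterfaceGroup],
    cut: float = DEFAULT_CLUSTER_CUT,
) -> list[BindingSite]:
    """Cluster interface groups into binding sites.

    Average-linkage hierarchical clustering on pairwise D = 1 − I_rel,
    cutting the tree at cophenetic distance ``cut`` (groups with cophenetic
    distance <= cut end up in one site, so a pair at exactly the cut merges).
    """
    if not groups:
        raise InvariantError("define_sites needs at least one interface group")
    ordered = sorted(groups, key=_sort_key)
    n = len(ordered)
    if n == 1:
        labels = np.array([1])
    else:
        condensed = np.array(
            [
                relative_intersection(ordered[i].fingerprint, ordered[j].fingerprint)[1]
                for i in range(n)
                for j in range(i + 1, n)
            ]
        )
        tree = linkage(condensed, method="average")
        labels = fcluster(tree, t=cut, criterion="distance")

    sites: list[BindingSite] = []
    for label in sorted(set(labels), key=lambda l: min(i for i in range(n) if labels[i] == l)):
        member_groups = [ordered[i] for i in range(n) if labels[i] == label]
        residues = frozenset().union(*(g.fingerprint for g in member_groups))
        members = tuple(m for g in member_groups for m in g.members)
        sites.append(
            BindingSite(
                site_id=f"site_{len(sites) + 1}",
                residues=residues,
                members=members,
                multiplicity=len(member_groups),
            )
        )
    return sites


def site_centroid(site: BindingSite, chain: Chain) -> np.ndarray:
    """Observed-site centroid on an evaluation chain.

    Unweighted mean of the heavy-atom coordinates of the site's residues
    found on the chain.  Residues of the site missing from the chain are
    skipped; if none are present the centroid is undefined.
    """
    by_up = chain.by_uniprot()
    coords = [
        by_up[r].heavy_coords() for r in sorted(site.residues) if r in by_up
    ]
    coords = [c for c in coords if len(c)]
    if not coords:
        raise UndefinedResultError(
            f"no residue of {site.site_id} present on chain {chain.chain_id}"
        )
    stacked = np.vstack(coords)
    return stacked.mean(axis=0)


def sites_from_structures(
    chains: Sequence[Chain],
    ligands,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    cut: float = DEFAULT_CLUSTER_CUT,
) -> list[BindingSite]:
    """Convenience pipeline: contacts → dedup → clustering for many structures.

    Each ligand is fingerprinted against every mapped chain of its own
    structure (contacts are unioned across chains of the assembly).
    """
    by_structure: dict[str, list[Chain]] = {}
    for ch in chains:
        by_structure.setdefault(ch.structure_id, []).append(ch)
    fingerprints: list[tuple[str, frozenset]] = []
    for lig in ligands:
        fp: set[int] = set()
        for ch in by_structure.get(lig.structure_id, []):
            fp |= compute_contacts(ch, lig.atoms, cutoff=cutoff)
        lig.fingerprint = frozenset(fp)
        fingerprints.append((lig.instance_id, lig.fingerprint))
    groups = deduplicate_interfaces(fingerprints)
    if not groups:
        return []
    return define_sites(groups, cut=cut)
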