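"""Readers and writers for structures, mappings, prediction tables and results.

Structure parsing is delegated to gemmi (PDB and mmCIF).  Residues are split
into polymer (standard amino acids) and ligand groups by their chemical
component; waters are discarded.  When an mmCIF file carries SIFTS
cross-references in the ``_atom_site.pdbx_sifts_xref_db_num`` field, the
UniProt residue numbers are attached to the chain residues at read time.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np
import pandas as pd

from .errors import EmptyStructureError, FormatError, MappingError
from .model import Atom, Chain, LigandInstance, PocketPrediction, ResidueScoreTrack

log = logging.getLogger(__name__)

PREDICTION_DIALECTS = ("full", "centroid_only", "residues_only")


@dataclass
class StructureData:
    """Parsed contents of one structure file."""

    structure_id: str
    chains: list[Chain] = field(default_factory=list)
    ligands: list[LigandInstance] = field(default_factory=list)


def _residue_kind(name: str) -> str:
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        if info.is_water():
            return "water"
        if info.is_amino_acid():
            return "polymer"
    return "ligand"


def _sifts_numbers(path: str) -> dict[tuple[str, str], int]:
    """Extract (auth chain, auth seq id + icode) -> UniProt number from mmCIF."""
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    table = block.find(
        "_atom_site.",
        ["auth_asym_id", "auth_seq_id", "?pdbx_PDB_ins_code", "?pdbx_sifts_xref_db_num"],
    )
    out: dict[tuple[str, str], int] = {}
    if not table or not table.has_column(3):
        return out
    for row in table:
        num = row[3]
        if num in (".", "?", ""):
            continue
        icode = row[2] if table.has_column(2) else "?"
        icode = "" if icode in (".", "?") else icode
        key = (row[0], f"{row[1]}{icode}")
        out[key] = int(num)
    return out


def read_structure(path: str | Path, fmt: Optional[str] = None) -> StructureData:
    """Read a PDB or mmCIF file into chains and ligand atom records.

    Parameters
    ----------
    path:
        Structure file.  Format is inferred from the extension unless ``fmt``
        (``"pdb"`` or ``"mmcif"``) is given.

    Returns
    -------
    StructureData
        Polymer chains (amino-acid residues) and non-polymer ligand groups.
        Waters are excluded; every non-water hetero group becomes one
        :class:`LigandInstance` (biological-relevance filtering is left to
        the caller).
    """
    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if fmt not in ("pdb", "mmcif"):
        raise FormatError(f"unknown structure format {fmt!r}")
    try:
        if fmt == "mmcif":
            structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc

    if len(structure) == 0:
        raise EmptyStructureError(f"{path}: no model in file")
    model = structure[0]

    sifts = _sifts_numbers(path) if fmt == "mmcif" else {}
    structure_id = (structure.name or path.stem).strip() or path.stem

    data = StructureData(structure_id=structure_id)
    ligand_counter: dict[str, int] = {}
    for g_chain in model:
        residues = []
        for g_res in g_chain:
            kind = _residue_kind(g_res.name)
            if kind == "water":
                continue
            icode = g_res.seqid.icode.strip()
            atoms = [
                Atom(
                    element=a.element.name,
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    residue_id=f"{g_chain.name}/{g_res.seqid.num}{icode}",
                    name=a.name,
                )
                for a in g_res
            ]
            if not atoms:
                continue
            if kind == "polymer":
                from .model import Residue

                residues.append(
                    Residue(
                        auth_seq_id=g_res.seqid.num,
                        icode=icode,
                        name=g_res.name,
                        atoms=atoms,
                        uniprot_num=sifts.get(
                            (g_chain.name, f"{g_res.seqid.num}{icode}")
                        ),
                    )
                )
            else:
                ligand_counter[g_res.name] = ligand_counter.get(g_res.name, 0) + 1
                data.ligands.append(
                    LigandInstance(
                        structure_id=structure_id,
                        ccd_code=g_res.name,
                        instance_id=(
                            f"{structure_id}_{g_res.name}_{g_chain.name}"
                            f"{g_res.seqid.num}{icode}"
                        ),
                        atoms=[a for a in atoms if a.is_heavy],
                    )
                )
        if residues:
            data.chains.append(
                Chain(
                    structure_id=structure_id,
                    chain_id=g_chain.name,
                    residues=residues,
                )
            )
    if not data.chains and not data.ligands:
        raise EmptyStructureError(f"{path}: no polymer or ligand atoms found")
    return data


def read_residue_mapping(path: str | Path) -> dict[tuple[str, str], int]:
    """Read a SIFTS-style TSV ``chain<TAB>auth_resnum<TAB>uniprot_resnum``.

    Duplicate (chain, residue) keys or non-integer UniProt targets raise
    :class:`MappingError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: mapping table needs 3 columns, got {df.shape[1]}")
    mapping: dict[tuple[str, str], int] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        key = (str(row[0]), str(row[1]))
        try:
            target = int(str(row[2]))
        except ValueError as exc:
            raise MappingError(
                f"{path} row {i}: UniProt residue number {row[2]!r} is not an integer"
            ) from exc
        if key in mapping and mapping[key] != target:
            raise MappingError(f"{path}: duplicate key {key} with conflicting targets")
        mapping[key] = target
    return mapping


def apply_residue_mapping(
    chain: Chain, mapping: dict[tuple[str, str], int]
) -> int:
    """Attach UniProt numbers to a chain in place; return unmapped count.

    Residues absent from the table keep ``uniprot_num=None`` (flagged
    unmapped); they never silently acquire numbers.
    """
    unmapped = 0
    for res in chain.residues:
        key = (chain.chain_id, res.auth_id)
        if key in mapping:
            res.uniprot_num = mapping[key]
        else:
            res.uniprot_num = None
            unmapped += 1
    if unmapped:
        log.warning(
            "chain %s: %d residue(s) without a UniProt mapping", chain.chain_id, unmapped
        )
    # re-validate uniqueness of the freshly assigned numbers
    Chain(
        structure_id=chain.structure_id,
        chain_id=chain.chain_id,
        residues=chain.residues,
        uniprot_acc=chain.uniprot_acc,
    )
    return unmapped


def read_predictions(path: str | Path, dialect: str = "full") -> list[PocketPrediction]:
    """Read a pocket prediction TSV.

    Dialects: ``full`` = method, chain, rank, score, cx, cy, cz, residues
    (";"-separated); ``centroid_only`` omits residues; ``residues_only``
    omits cx..cz.  A header row is required.  Empty rank/score fields are
    stored as absent.
    """
    if dialect not in PREDICTION_DIALECTS:
        raise FormatError(f"unknown predictions dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    preds: list[PocketPrediction] = []
    for i, row in df.iterrows():
        rank = row.get("rank")
        score = row.get("score")
        rank = int(rank) if rank not in (None, "", "NA") and not pd.isna(rank) else None
        score = (
            float(score) if score not in (None, "", "NA") and not pd.isna(score) else None
        )
        centroid = None
        residues = None
        if dialect in ("full", "centroid_only"):
            cx, cy, cz = row.get("cx"), row.get("cy"), row.get("cz")
            if not any(pd.isna(v) or v in ("", None) for v in (cx, cy, cz)):
                centroid = np.array([float(cx), float(cy), float(cz)])
        if dialect in ("full", "residues_only"):
            raw = row.get("residues")
            if raw is not None and not pd.isna(raw) and str(raw).strip():
                residues = frozenset(int(r) for r in str(raw).split(";") if r.strip())
        if centroid is None and residues is None:
            raise FormatError(
                f"{path} row {i}: prediction has neither centroid nor residues"
            )
        preds.append(
            PocketPrediction(
                method=str(row["method"]),
                chain_id=str(row["chain"]),
                pocket_id=str(row.get("pocket_id", f"{row['method']}_{i}")),
                rank=rank,
                score=score,
                centroid=centroid,
                residues=residues,
            )
        )
    return preds


def write_predictions(preds: list[PocketPrediction], path: str | Path) -> None:
    """Write predictions in the ``full`` TSV dialect (round-trips with the reader)."""
    rows = []
    for p in preds:
        rows.append(
            {
                "method": p.method,
                "chain": p.chain_id,
                "pocket_id": p.pocket_id,
                "rank": "" if p.rank is None else p.rank,
                "score": "" if p.score is None else repr(p.score),
                "cx": "" if p.centroid is None else repr(float(p.centroid[0])),
                "cy": "" if p.centroid is None else repr(float(p.centroid[1])),
                "cz": "" if p.centroid is None else repr(float(p.centroid[2])),
                "residues": ""
                if p.residues is None
                else ";".join(str(r) for r in sorted(p.residues)),
            }
        )
    cols = ["method", "chain", "pocket_id", "rank", "score", "cx", "cy", "cz", "residues"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_residue_scores(
    path: str | Path,
) -> tuple[ResidueScoreTrack, Optional[np.ndarray], list[int]]:
    """Read a residue score TSV: ``chain, uniprot_resnum, score[, score_2..score_n]``.

    Returns the single-column track (for multi-column input, the first
    column), the per-model matrix when the file carries an ensemble
    (>= 2 score columns) and the residue order of the matrix rows.
    """
    df = pd.read_csv(path, sep="\t")
    score_cols = [c for c in df.columns if c.startswith("score")]
    if not score_cols:
        raise FormatError(f"{path}: no score columns found")
    for c in score_cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()].tolist()
            raise FormatError(f"{path}: non-numeric score in rows {bad}")
        if df[c].isna().any():
            bad = df.index[df[c].isna()].tolist()
            raise FormatError(f"{path}: missing score in rows {bad}")
    chain_id = str(df["chain"].iloc[0]) if len(df) else ""
    residues = [int(r) for r in df["uniprot_resnum"]]
    first = dict(zip(residues, (float(v) for v in df[score_cols[0]])))
    probability_like = all(0.0 <= v <= 1.0 for v in first.values())
    track = ResidueScoreTrack(
        chain_id=chain_id, scores=first, probability_like=probability_like
    )
    matrix = df[score_cols].to_numpy(dtype=float) if len(score_cols) > 1 else None
    return track, matrix, residues


def write_sites(sites, path: str | Path) -> None:
    """Write binding sites as TSV: id, residues, members, multiplicity and
    (when present) the evaluation-chain centroid."""
    rows = []
    for s in sites:
        c = getattr(s, "centroid", None)
        rows.append(
            {
                "site_id": s.site_id,
                "residues": ";".join(str(r) for r in sorted(s.residues)),
                "members": ";".join(s.members),
                "multiplicity": s.multiplicity,
                "cx": "" if c is None else repr(float(c[0])),
                "cy": "" if c is None else repr(float(c[1])),
                "cz": "" if c is None else repr(float(c[2])),
            }
        )
    cols = ["site_id", "residues", "members", "multiplicity", "cx", "cy", "cz"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path):
    """Read a sites TSV written by :func:`write_sites`."""
    from .sites import BindingSite

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    sites = []
    for row in df.itertuples(index=False):
        centroid = None
        if getattr(row, "cx", "") != "":
            centroid = np.array([float(row.cx), float(row.cy), float(row.cz)])
        sites.append(
            BindingSite(
                site_id=str(row.site_id),
                residues=frozenset(int(r) for r in row.residues.split(";") if r),
                members=tuple(m for m in row.members.split(";") if m),
                multiplicity=int(row.multiplicity),
                centroid=centroid,
            )
        )
    return sites


def write_results(records: list[dict], path: str | Path, fmt: str = "tsv") -> None:
    """Write generic result records as TSV or JSON (round-trip stable)."""
    path = Path(path)
    if fmt == "tsv":
        pd.DataFrame(records).to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        path.write_text(json.dumps(records, indent=2, sort_keys=True) + "\n")
    else:
        raise FormatError(f"unknown results format {fmt!r}")


def write_chain_pdb(chain, path: str | Path, ligands=()) -> None:
    """Write a chain (and optional ligand groups) as a minimal PDB file."""
    lines = []
    serial = 1
    for res in chain.residues:
        for atom in res.atoms:
            name = (atom.name or atom.element)[:4]
            x, y, z = atom.coords
            lines.append(
                f"ATOM  {serial:5d} {name:>4s} {res.name:>3s} "
                f"{chain.chain_id:1s}{res.auth_seq_id:4d}{(res.icode or ' '):1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{atom.element:>2s}"
            )
            serial += 1
    for lig_num, lig in enumerate(ligands, start=1):
        for a_idx, atom in enumerate(lig.atoms, start=1):
            x, y, z = atom.coords
            lines.append(
                f"HETATM{serial:5d} {f'{atom.element}{a_idx}'[:4]:>4s} "
                f"{lig.ccd_code:>3s} L{lig_num:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{atom.element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_results(path: str | Path, fmt: str = "tsv") -> list[dict]:
    path = Path(path)
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t").to_dict(orient="records")
    if fmt == "json":
        return json.loads(path.read_text())
    raise FormatError(f"unknown results format {fmt!r}")
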