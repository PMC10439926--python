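"""Readers and writers: TSV feature tables, variant annotation tables, PDB CA
extraction, and placement of multiple structures along the 3D-space bisector.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from mitopath.datamodel import (
    FeatureGroup,
    FeatureTable,
    ResidueSite,
    Status,
    VariantRecord,
)

logger = logging.getLogger(__name__)

BISECTOR = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)


def read_feature_table(
    path: str | Path,
    id_column: str = "variant_id",
    feature_groups: Mapping[str, FeatureGroup | str] | None = None,
    spatial_flags: Iterable[str] = (),
    missing_token: str = "",
    sep: str = "\t",
) -> FeatureTable:
    """Read a delimited feature table.

    Cells equal to ``missing_token`` (default: empty) become missing; cells
    that fail numeric parsing also become missing, with a logged warning
    count. The id column must exist and contain no duplicates.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if id_column not in df.columns:
        raise ValueError(f"{path}: id column {id_column!r} not found")
    if df[id_column].duplicated().any():
        dupes = df[id_column][df[id_column].duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate variant ids: {dupes}")
    df = df.set_index(id_column)
    df.index.name = None
    df = df.replace(missing_token, np.nan)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    n_unparseable = int((numeric.isna() & df.notna()).to_numpy().sum())
    if n_unparseable:
        logger.warning("%s: %d unparseable numeric cells set to missing", path, n_unparseable)
    groups = {
        name: FeatureGroup(group) for name, group in (feature_groups or {}).items()
    }
    return FeatureTable(numeric, groups, spatial_flags)


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    id_column: str = "variant_id",
    missing_token: str = "",
    sep: str = "\t",
) -> None:
    """Write a feature table; round-trips through :func:`read_feature_table`.

    Floats are written with ``repr`` precision so values survive bit-identically.
    """
    df = table.values.copy()
    out = df.map(lambda v: missing_token if pd.isna(v) else repr(float(v)))
    out.index.name = id_column
    out.to_csv(path, sep=sep)


def read_variant_table(path: str | Path, sep: str = "\t") -> list[VariantRecord]:
    """Read a variant annotation table.

    Expected columns: pos, ref, alt, status, clingen_codes (comma-joined),
    synergistic (0/1), plus any number of ``af_hom_<source>`` /
    ``af_het_<source>`` pairs.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    hom_cols = [c for c in df.columns if c.startswith("af_hom_")]
    records = []
    for _, row in df.iterrows():
        af: dict[str, tuple[float, float]] = {}
        for hom_col in hom_cols:
            source = hom_col.removeprefix("af_hom_")
            het_col = f"af_het_{source}"
            hom = row.get(hom_col, "")
            het = row.get(het_col, "")
            if hom != "" and het != "":
                af[source] = (float(hom), float(het))
        codes = frozenset(
            c.strip() for c in row.get("clingen_codes", "").split(",") if c.strip()
        )
        records.append(
            VariantRecord(
                mt_position=int(row["pos"]),
                ref_allele=row["ref"],
                alt_allele=row["alt"],
                gene=row.get("gene", ""),
                protein_change=row.get("protein_change", ""),
                status=Status(row.get("status", "none") or "none"),
                clingen_codes=codes,
                synergistic_or_conflicting=row.get("synergistic", "0") in ("1", "true", "True"),
                af=af,
            )
        )
    return records


def read_structure_ca(
    pdb_path: str | Path,
    chain_map: Mapping[str, str],
) -> list[ResidueSite]:
    """Extract one :class:`ResidueSite` per residue from a PDB file.

    ``chain_map`` maps chain ids to a complex/protein label; only listed
    chains are read. The CA atom locates each residue; residues without a CA
    are skipped with a warning. For alternate locations the highest-occupancy
    conformer wins, ties going to the first listed.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("s", str(pdb_path))
    model = next(structure.get_models())
    present = {chain.id for chain in model}
    wanted = set(chain_map)
    if not wanted & present:
        raise ValueError(
            f"{pdb_path}: none of the requested chains {sorted(wanted)} present "
            f"(found {sorted(present)})"
        )
    sites: list[ResidueSite] = []
    n_skipped = 0
    for chain in model:
        if chain.id not in chain_map:
            continue
        complex_id = chain_map[chain.id]
        for residue in chain:
            hetflag, resseq, _icode = residue.id
            if hetflag.strip():
                continue  # heteroatoms are not protein residues
            ca = _best_ca(residue)
            if ca is None:
                n_skipped += 1
                continue
            x, y, z = (float(v) for v in ca)
            sites.append(ResidueSite(complex_id, chain.id, int(resseq), (x, y, z)))
    if n_skipped:
        logger.warning("%s: %d residues without CA skipped", pdb_path, n_skipped)
    return sites


def _best_ca(residue) -> np.ndarray | None:
    if "CA" not in residue:
        return None
    atom = residue["CA"]
    if atom.is_disordered():
        # highest occupancy; Biopython lists altlocs in file order, and
        # max() keeps the first on ties
        children = atom.disordered_get_list()
        best = max(children, key=lambda a: a.get_occupancy() or 0.0)
        return best.get_coord()
    return atom.get_coord()


def place_on_bisector(
    structures: Sequence[list[ResidueSite]],
    d: float = 20.0,
) -> list[list[ResidueSite]]:
    """Translate each structure onto the bisector of 3D space, 3*d apart.

    Structure k's centroid lands at distance ``3*d*k`` along the unit
    direction (1,1,1)/sqrt(3) from the origin (structure 0 centered there).
    Translations are rigid: within-structure geometry is untouched.
    """
    if d <= 0:
        raise ValueError(f"spacing d must be positive, got {d}")
    if not structures:
        raise ValueError("need at least one structure")
    placed: list[list[ResidueSite]] = []
    for k, sites in enumerate(structures):
        coords = np.array([s.ca_coord for s in sites], dtype=float)
        centroid = coords.mean(axis=0)
        target = 3.0 * d * k * BISECTOR
        shift = target - centroid
        placed.append(
            [
                ResidueSite(
                    s.complex_id,
                    s.chain,
                    s.residue_index,
                    tuple(np.asarray(s.ca_coord) + shift),
                    s.mean_score,
                )
                for s in sites
            ]
        )
    return placed
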