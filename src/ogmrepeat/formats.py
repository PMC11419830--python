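"""Readers and writers for the OGM text interchange formats.

CMAP (reference/consensus label maps), BNX 1.3 (raw labelled molecules) and
XMAP 0.2 (molecule-to-reference alignments) are tab-separated text formats;
positions are written as floats with one decimal, as produced in the wild.
Only label channel 1 is handled.  FASTA reading goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

from Bio import SeqIO

from .labelmap import ReferenceLabelMap

if TYPE_CHECKING:  # avoid import cycle at runtime typing only
    from .align import MoleculeAlignment
    from .simulate import Molecule

__all__ = [
    "read_fasta",
    "read_cmap",
    "write_cmap",
    "read_bnx",
    "write_bnx",
    "read_xmap",
    "write_xmap",
]


class FormatError(ValueError):
    """Malformed OGM interchange file."""


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read all records of a FASTA file as {name: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# CMAP

_CMAP_HEADER = """\
# CMAP File Version:\t0.2
# Label Channels:\t1
# Nickase Recognition Site 1:\t{motif}
# Number of Consensus Maps:\t{n_maps}
#h CMapId\tContigLength\tNumSites\tSiteID\tLabelChannel\tPosition
#f int\tfloat\tint\tint\tint\tfloat
"""


def write_cmap(
    maps: Sequence[ReferenceLabelMap] | ReferenceLabelMap,
    path: str | Path,
    motif: str = "CTTAAG",
) -> None:
    """Write label maps as CMAP 0.2.

    CMapIds are assigned 1..N in order.  Following convention, a final
    channel-0 site at the contig end terminates each map.
    """
    if isinstance(maps, ReferenceLabelMap):
        maps = [maps]
    with open(path, "w") as fh:
        fh.write(_CMAP_HEADER.format(motif=motif, n_maps=len(maps)))
        for cmap_id, m in enumerate(maps, start=1):
            n = len(m.labels)
            for site_id, (_, pos) in enumerate(m.labels, start=1):
                fh.write(
                    f"{cmap_id}\t{float(m.contig_length):.1f}\t{n}\t"
                    f"{site_id}\t1\t{float(pos):.1f}\n"
                )
            fh.write(
                f"{cmap_id}\t{float(m.contig_length):.1f}\t{n}\t"
                f"{n + 1}\t0\t{float(m.contig_length):.1f}\n"
            )


def read_cmap(path: str | Path) -> dict[str, ReferenceLabelMap]:
    """Read a CMAP file; returns {str(CMapId): ReferenceLabelMap}.

    Channel-0 terminal rows are ignored; positions are rounded to integer
    bp.  Label ids are the CMAP SiteIDs.
    """
    per_map: dict[str, list[tuple[int, int]]] = {}
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 6 CMAP columns"
                )
            cmap_id, contig_len, _, site_id, channel, pos = parts[:6]
            if int(channel) != 1:
                continue
            per_map.setdefault(cmap_id, []).append(
                (int(site_id), round(float(pos)))
            )
            lengths[cmap_id] = round(float(contig_len))
    return {
        cid: ReferenceLabelMap(cid, lengths[cid], tuple(sorted(sites, key=lambda s: s[1])))
        for cid, sites in per_map.items()
    }


# ---------------------------------------------------------------------------
# BNX

_BNX_HEADER = """\
# BNX File Version:\t1.3
# Label Channels:\t1
# Nickase Recognition Site 1:\tCTTAAG;green_01
#0h\tLabelChannel\tMoleculeId\tLength
#0f\tint\tint\tfloat
#1h\tLabelChannel\tLabelPositions[N]
#1f\tint\tfloat
"""


def write_bnx(molecules: Sequence["Molecule"], path: str | Path) -> None:
    """Write molecules as BNX 1.3 (channel 1; no quality Q lines).

    The 1-line lists label positions followed, by convention, by the
    molecule length as its final value.
    """
    with open(path, "w") as fh:
        fh.write(_BNX_HEADER)
        for mol in molecules:
            fh.write(f"0\t{mol.molecule_id}\t{float(mol.length):.1f}\n")
            sites = "\t".join(f"{float(p):.1f}" for p in mol.label_positions)
            tail = f"{sites}\t" if sites else ""
            fh.write(f"1\t{tail}{float(mol.length):.1f}\n")


def read_bnx(path: str | Path) -> list["Molecule"]:
    """Read a BNX file back into molecules.

    Only the 0 (molecule) and 1 (channel-1 label) lines are interpreted; QX
    quality lines are ignored.  A malformed header or a 1-line without a
    preceding 0-line raises :class:`FormatError` naming the line.
    """
    from .simulate import Molecule  # deferred: avoids import cycle

    molecules: list[Molecule] = []
    pending: tuple[int, int] | None = None
    saw_version = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.lower().startswith("# bnx file version"):
                    saw_version = True
                continue
            if not saw_version:
                raise FormatError(
                    f"{path}: line {lineno}: data before '# BNX File Version' header"
                )
            fieldsep = line.split("\t")
            tag = fieldsep[0]
            if tag == "0":
                if len(fieldsep) < 3:
                    raise FormatError(
                        f"{path}: line {lineno}: 0-line needs MoleculeId and Length"
                    )
                pending = (int(fieldsep[1]), round(float(fieldsep[2])))
            elif tag == "1":
                if pending is None:
                    raise FormatError(
                        f"{path}: line {lineno}: 1-line without preceding 0-line"
                    )
                mol_id, length = pending
                vals = [round(float(v)) for v in fieldsep[1:] if v]
                if vals and vals[-1] == length:
                    vals = vals[:-1]  # trailing molecule-length sentinel
                molecules.append(
                    Molecule(mol_id, length, tuple(vals))
                )
                pending = None
            elif tag.startswith("Q"):
                continue
            else:
                raise FormatError(
                    f"{path}: line {lineno}: unrecognised line tag {tag!r}"
                )
    return molecules


# ---------------------------------------------------------------------------
# XMAP

_XMAP_COLUMNS = (
    "XmapEntryID",
    "QryContigID",
    "RefContigID",
    "QryStartPos",
    "QryEndPos",
    "RefStartPos",
    "RefEndPos",
    "Orientation",
    "Confidence",
    "HitEnum",
    "QryLen",
    "RefLen",
    "LabelChannel",
    "Alignment",
)

_XMAP_HEADER = (
    "# XMAP File Version:\t0.2\n"
    "# Label Channels:\t1\n"
    "#h " + "\t".join(_XMAP_COLUMNS) + "\n"
    "#f int\tint\tint\tfloat\tfloat\tfloat\tfloat\tstring\tfloat\tstring\t"
    "float\tfloat\tint\tstring\n"
)


def write_xmap(
    alignments: Sequence["MoleculeAlignment"],
    path: str | Path,
    ref: ReferenceLabelMap,
    molecules: dict[int, "Molecule"],
    ref_contig_id: int = 1,
) -> None:
    """Write alignments as XMAP 0.2 against one reference map."""
    pos_of = dict(ref.labels)
    with open(path, "w") as fh:
        fh.write(_XMAP_HEADER)
        for entry, aln in enumerate(alignments, start=1):
            mol = molecules[aln.molecule_id]
            ref_sites = [pos_of[r] for r, _ in aln.pairs]
            qry_sites = [mol.label_positions[q - 1] for _, q in aln.pairs]
            pairs_str = "".join(f"({r},{q})" for r, q in aln.pairs)
            fh.write(
                f"{entry}\t{aln.molecule_id}\t{ref_contig_id}\t"
                f"{float(qry_sites[0]):.1f}\t{float(qry_sites[-1]):.1f}\t"
                f"{float(ref_sites[0]):.1f}\t{float(ref_sites[-1]):.1f}\t"
                f"{aln.orientation}\t{aln.confidence:.2f}\t"
                f"{len(aln.pairs)}M\t{float(mol.length):.1f}\t"
                f"{float(ref.contig_length):.1f}\t1\t{pairs_str}\n"
            )


def read_xmap(path: str | Path) -> list["MoleculeAlignment"]:
    """Read an XMAP 0.2 file into alignments.

    The Alignment column's "(refSiteID,qrySiteID)" pairs are parsed as
    written; per the format, reference site ids always increase along the
    row while query site ids decrease for '-' orientation rows.
    """
    import warnings

    from .align import MoleculeAlignment  # deferred: avoids import cycle

    alignments: list[MoleculeAlignment] = []
    columns: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#h"):
                columns = line[2:].strip().split("\t")
                continue
            if line.startswith("#"):
                if line.lower().startswith("# xmap file version"):
                    version = line.split("\t")[-1].strip()
                    if version != "0.2":
                        warnings.warn(
                            f"{path}: XMAP version {version}; parsing best-effort"
                        )
                continue
            parts = line.split("\t")
            cols = columns if columns is not None else list(_XMAP_COLUMNS)
            row = dict(zip(cols, parts))
            if "Alignment" not in row:
                raise FormatError(
                    f"{path}: line {lineno}: missing Alignment column"
                )
            pairs = _parse_pairs(row["Alignment"], path, lineno)
            alignments.append(
                MoleculeAlignment(
                    molecule_id=int(row["QryContigID"]),
                    contig=str(row["RefContigID"]),
                    orientation=row["Orientation"],
                    pairs=pairs,
                    confidence=float(row.get("Confidence", "nan")),
                )
            )
    return alignments


def _parse_pairs(
    text: str, path: str | Path, lineno: int
) -> tuple[tuple[int, int], ...]:
    pairs = []
    for chunk in text.replace(")(", ")\t(").split("\t"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if not (chunk.startswith("(") and chunk.endswith(")")):
            raise FormatError(
                f"{path}: line {lineno}: bad Alignment pair {chunk!r}"
            )
        r, q = chunk[1:-1].split(",")
        pairs.append((int(r), int(q)))
    return tuple(pairs)
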