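"""File formats: FASTA and GenBank via Biopython, JSON registries.

GenBank records carry the construct topology in the LOCUS line and
each :class:`~unskit.seqcore.Feature` as a ``misc_feature`` with a
``label`` qualifier, so write-then-read preserves the sequence exactly
and features up to coordinate equality. Records are written with a
fixed date so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .parts_model import Part
from .seqcore import DnaSequence
from .uns_designer import UnsSet

__all__ = [
    "to_seqrecord",
    "from_seqrecord",
    "write_genbank",
    "read_genbank",
    "write_fasta",
    "read_fasta",
    "write_uns_fasta",
    "read_uns_fasta",
    "read_part_registry",
]

_FIXED_DATE = "01-JAN-1980"  # reproducible output


def to_seqrecord(seq: DnaSequence) -> SeqRecord:
    rec = SeqRecord(Seq(seq.residues), id=seq.name, name=seq.name[:16], description=seq.name)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if seq.is_circular else "linear"
    rec.annotations["date"] = _FIXED_DATE
    for f in seq.features:
        if f.end <= f.start:
            continue  # wrapped-origin spans are not representable simply
        rec.features.append(
            SeqFeature(
                SimpleLocation(f.start, f.end, strand=f.strand),
                type="misc_feature",
                qualifiers={"label": [f.label]},
            )
        )
    return rec


def from_seqrecord(rec: SeqRecord) -> DnaSequence:
    if len(rec.seq) == 0:
        raise ValueError(f"record {rec.id!r} has an empty sequence")
    topo = rec.annotations.get("topology", "linear")
    seq = DnaSequence(str(rec.seq), topo, rec.description or rec.id)
    for f in rec.features:
        if f.type != "misc_feature":
            continue
        label = f.qualifiers.get("label", [f.type])[0]
        seq.annotate(label, int(f.location.start), int(f.location.end), f.location.strand or 1)
    return seq


def write_genbank(seqs: DnaSequence | list[DnaSequence], path: str | Path) -> None:
    if isinstance(seqs, DnaSequence):
        seqs = [seqs]
    SeqIO.write([to_seqrecord(s) for s in seqs], str(path), "genbank")


def read_genbank(path: str | Path) -> list[DnaSequence]:
    return [from_seqrecord(r) for r in SeqIO.parse(str(path), "genbank")]


def write_fasta(seqs: list[DnaSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.name}\n")
            for i in range(0, len(s.residues), 70):
                fh.write(s.residues[i : i + 70] + "\n")


def read_fasta(path: str | Path) -> list[DnaSequence]:
    return [
        DnaSequence(str(r.seq), "linear", r.id)
        for r in SeqIO.parse(str(path), "fasta")
    ]


def write_uns_fasta(uns_set: UnsSet, path: str | Path) -> None:
    """Designed set as FASTA, record ids = UNS names, design order."""
    write_fasta(
        [DnaSequence(seq, "linear", name) for name, seq in uns_set.members.items()],
        path,
    )


def read_uns_fasta(path: str | Path, config=None) -> UnsSet:
    from .uns_designer import DesignConfig, _cross_matrix

    members = {s.name: s.residues for s in read_fasta(path)}
    if "UNSX" not in members:
        raise ValueError(f"{path}: UNS FASTA must contain a UNSX record")
    return UnsSet(members, _cross_matrix(list(members.values())), config or DesignConfig())


def read_part_registry(path: str | Path) -> list[Part]:
    """Part registry JSON: list of {name, role, sequence | fasta}.

    ``fasta`` paths are resolved relative to the registry file.
    """
    path = Path(path)
    try:
        entries = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(entries, list):
        raise ValueError(f"{path}: registry must be a JSON list of parts")
    parts = []
    for i, e in enumerate(entries):
        try:
            name, role = e["name"], e["role"]
        except (TypeError, KeyError) as exc:
            raise ValueError(f"{path}: entry {i} lacks name/role") from exc
        if "sequence" in e:
            seq = DnaSequence(e["sequence"], "linear", name)
        elif "fasta" in e:
            recs = read_fasta(path.parent / e["fasta"])
            if not recs:
                raise ValueError(f"{path}: entry {name}: empty FASTA {e['fasta']}")
            seq = DnaSequence(recs[0].residues, "linear", name)
        else:
            raise ValueError(f"{path}: entry {name} needs 'sequence' or 'fasta'")
        parts.append(Part(name, role, seq))
    return parts
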