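"""Labelled amplicon sequence records and FASTA round-tripping.

Every node of a similarity network starts as a :class:`SequenceRecord`: a
nucleotide sequence carrying the labels that downstream analyses test for
structure — molecule (DNA/cDNA), epoch of discovery (cultured isolate,
earlier environmental survey, or the new survey), sampling site and habitat.

Labels are serialized into the FASTA header using a small ``key=value``
dialect (header dialect version 1)::

    >seq001|molecule=DNA|epoch=new_survey|site=site3|habitat=DCM

Absent fields are omitted; cultured-isolate records carry no site or
habitat by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

EPOCHS = ("cultured", "prior_env", "new_survey")
HABITATS = ("subsurface", "DCM", "sediment")
MOLECULES = ("DNA", "cDNA")

#: IUPAC nucleotide codes accepted in input sequences.
IUPAC_NT = frozenset("ACGTUNRYSWKMBDHV")

_HEADER_KEYS = ("molecule", "epoch", "site", "habitat", "truth_species")


@dataclass(frozen=True)
class SequenceRecord:
    """One labelled amplicon sequence (a node-to-be).

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    sequence : str
        Nucleotide string; upper-cased on construction.
    molecule : str
        ``"DNA"`` or ``"cDNA"``.
    epoch : str
        ``"cultured"`` (reference isolate), ``"prior_env"`` (earlier
        environmental survey) or ``"new_survey"``.
    site, habitat : str or None
        Sampling labels; absent (``None``) for cultured isolates.
    truth_species : str or None
        Planted species id; synthetic datasets only.
    """

    id: str
    sequence: str
    molecule: str = "DNA"
    epoch: str = "new_survey"
    site: Optional[str] = None
    habitat: Optional[str] = None
    truth_species: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.molecule not in MOLECULES:
            raise ValueError(f"record {self.id!r}: unknown molecule {self.molecule!r}")
        if self.epoch not in EPOCHS:
            raise ValueError(f"record {self.id!r}: unknown epoch {self.epoch!r}")
        if self.epoch == "cultured" and (self.site is not None or self.habitat is not None):
            raise ValueError(
                f"record {self.id!r}: cultured records carry no site/habitat labels"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def labels(self) -> dict:
        """Non-sequence attributes as a plain dict (``None`` values kept)."""
        d = asdict(self)
        d.pop("sequence")
        return d


def _check_unique_ids(records: Sequence[SequenceRecord]) -> None:
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)


def make_header(rec: SequenceRecord) -> str:
    """FASTA header (without ``>``) for ``rec`` in the package dialect."""
    parts = [rec.id]
    for key in _HEADER_KEYS:
        value = getattr(rec, key)
        if value is not None:
            parts.append(f"{key}={value}")
    return "|".join(parts)


def parse_header(header: str) -> dict:
    """Parse a header produced by :func:`make_header` into record kwargs."""
    fields = header.split("|")
    kwargs: dict = {"id": fields[0]}
    for part in fields[1:]:
        if "=" not in part:
            raise ValueError(f"malformed header field {part!r} in {header!r}")
        key, _, value = part.partition("=")
        if key not in _HEADER_KEYS:
            raise ValueError(f"unknown header key {key!r} in {header!r}")
        kwargs[key] = value
    return kwargs


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    """Write records as FASTA with labels encoded in the headers."""
    if not records:
        raise ValueError("refusing to write an empty FASTA")
    _check_unique_ids(records)
    seqrecords = [
        SeqRecord(Seq(rec.sequence), id=make_header(rec), description="")
        for rec in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA written by :func:`write_fasta` (or any plain FASTA).

    Headers without the ``key=value`` dialect yield records with default
    labels (DNA, new_survey, no site/habitat).
    """
    records = []
    for sr in SeqIO.parse(str(path), "fasta"):
        kwargs = parse_header(sr.id)
        records.append(SequenceRecord(sequence=str(sr.seq), **kwargs))
    _check_unique_ids(records)
    return records
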