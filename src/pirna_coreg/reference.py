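"""piRNA reference handling: piRNABank-style records and FASTA round trips."""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["PiRNAReference", "canonical_pirna_id", "MIN_PIRNA_LEN", "MAX_PIRNA_LEN"]

MIN_PIRNA_LEN = 16
MAX_PIRNA_LEN = 36

_ID_RE = re.compile(r"^(?:(?P<sp>[A-Za-z]{3})[_-])?piR[_-]?(?P<num>\d+)$", re.IGNORECASE)


def canonical_pirna_id(raw: str) -> str:
    """Normalise piRNA id spellings to the accession form.

    ``piR-823``, ``piR_000823`` and ``hsa_piR_000823`` all denote the same
    piRNABank record; they are canonicalised to ``hsa_piR_000823`` (species
    prefix kept when one is present, number zero-padded to six digits).
    Ids that do not look like piRNA accessions (e.g. ``RNU6-6P``) pass
    through unchanged.
    """
    m = _ID_RE.match(raw.strip())
    if m is None:
        return raw.strip()
    species = (m.group("sp") or "hsa").lower()
    return f"{species}_piR_{int(m.group('num')):06d}"


@dataclass(frozen=True)
class PiRNARecord:
    id: str
    sequence: str  # DNA alphabet (T-encoded)

    @property
    def length(self) -> int:
        return len(self.sequence)


class PiRNAReference:
    """Ordered collection of unique piRNA sequence records."""

    def __init__(self, records):
        self.records = list(records)
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("reference ids must be unique")
        for r in self.records:
            if not (MIN_PIRNA_LEN <= r.length <= MAX_PIRNA_LEN):
                raise ValueError(
                    f"{r.id}: length {r.length} outside [{MIN_PIRNA_LEN}, {MAX_PIRNA_LEN}]"
                )
        self._by_id = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def __getitem__(self, feature_id: str) -> PiRNARecord:
        return self._by_id[feature_id]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def lengths(self) -> dict[str, int]:
        return {r.id: r.length for r in self.records}

    # -- FASTA -------------------------------------------------------------

    def to_fasta(self, path) -> None:
        recs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in self.records]
        SeqIO.write(recs, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path) -> "PiRNAReference":
        records = [
            PiRNARecord(rec.id, str(rec.seq).upper().replace("U", "T"))
            for rec in SeqIO.parse(str(path), "fasta")
        ]
        if not records:
            raise ValueError(f"no records in FASTA {path}")
        return cls(records)
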