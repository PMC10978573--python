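"""Shared I/O: sequence records, FASTA and metadata-CSV reading/writing, run manifests.

The canonical alphabet is the 20 standard amino acids. Ambiguity codes
(B/Z/J/X/U/O) are tolerated on input and mapped to UNK downstream, with a
warning, because NGS-derived antibody data routinely contains them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger("vhhlm")

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
AMBIGUOUS = frozenset("BZJXUO")

_GAP_RE = re.compile(r"[.\-]")


@dataclasses.dataclass
class SequenceRecord:
    """An immunoglobulin variable-domain sequence plus optional metadata."""

    id: str
    sequence: str
    species: str | None = None
    germline_gene: str | None = None
    measurement: float | None = None
    n_mutations: int | None = None
    extras: dict = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)


def validate_sequence(seq: str, *, allow_ambiguous: bool = True) -> str:
    """Upper-case, strip gap characters, and check the alphabet.

    Raises ValueError listing offending symbols if anything outside the
    canonical + ambiguity alphabet remains.
    """
    cleaned = _GAP_RE.sub("", seq.upper())
    allowed = AA_SET | (AMBIGUOUS if allow_ambiguous else frozenset())
    bad = sorted(set(cleaned) - allowed)
    if bad:
        raise ValueError(f"non-canonical residues {bad} in sequence")
    if len(cleaned) != len(seq):
        logger.warning("stripped %d gap characters from sequence", len(seq) - len(cleaned))
    return cleaned


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read amino-acid FASTA into records.

    Duplicate ids are suffixed ``_2``, ``_3``, ... with a logged warning;
    sequences are upper-cased and gap characters stripped.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}_{seen[rid]}"
            logger.warning("duplicate FASTA id %r renamed to %r", rid, new_id)
            rid = new_id
        else:
            seen[rid] = 1
        records.append(SequenceRecord(id=rid, sequence=validate_sequence(str(rec.seq))))
    if not records:
        raise ValueError(f"no sequences in FASTA file {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(Path(path)), "fasta")


_NUMBER_RE = re.compile(r"[-+]?\d+(\.\d+)?")


def read_metadata_csv(path: str | Path, known_ids: set[str] | None = None) -> dict[str, dict]:
    """Read a metadata sidecar CSV (must have an ``id`` column) into id -> row dict.

    Typed fields (``measurement``, ``property_value``, ``n_mutations``) are
    parsed numerically, tolerating unit suffixes; other columns stay strings.
    Rows whose id is absent from ``known_ids`` (when given) are flagged with a
    warning but retained.
    """
    df = pd.read_csv(path, dtype=str)
    if "id" not in df.columns:
        raise ValueError(f"metadata CSV {path} lacks an 'id' column")
    out: dict[str, dict] = {}
    for _, row in df.iterrows():
        rid = row["id"]
        meta = {}
        for col in df.columns:
            if col == "id":
                continue
            val = row[col]
            if pd.isna(val):
                meta[col] = None
            elif col in ("measurement", "property_value", "n_mutations"):
                m = _NUMBER_RE.search(str(val))
                meta[col] = float(m.group(0)) if m else None
            else:
                meta[col] = str(val)
        if known_ids is not None and rid not in known_ids:
            logger.warning("metadata row id %r not present in sequence set", rid)
        out[rid] = meta
    return out


def attach_metadata(records: list[SequenceRecord], meta: dict[str, dict]) -> list[SequenceRecord]:
    """Merge a metadata map (from :func:`read_metadata_csv`) onto records in place."""
    for rec in records:
        m = meta.get(rec.id)
        if m is None:
            continue
        rec.species = m.get("species", rec.species)
        rec.germline_gene = m.get("germline_gene", rec.germline_gene)
        v = m.get("measurement", m.get("property_value"))
        if v is not None:
            rec.measurement = float(v)
        if m.get("n_mutations") is not None:
            rec.n_mutations = int(m["n_mutations"])
        rec.extras.update({k: v for k, v in m.items()
                           if k not in ("species", "germline_gene", "measurement",
                                        "property_value", "n_mutations")})
    return records


def write_metadata_csv(records: Iterable[SequenceRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({"id": r.id, "species": r.species, "germline_gene": r.germline_gene,
                     "n_mutations": r.n_mutations, "property_value": r.measurement})
    pd.DataFrame(rows).to_csv(path, index=False)


def dataset_manifest(path: str | Path, name: str, n_sequences: int,
                     source: str = "simulated") -> dict:
    """Checksum-bearing bookkeeping entry for a dataset file."""
    data = Path(path).read_bytes()
    return {"name": name, "n_sequences": n_sequences, "source": source,
            "checksum": hashlib.sha256(data).hexdigest()}


def write_run_snapshot(out_dir: str | Path, config: dict,
                       manifests: list[dict] | None = None) -> None:
    """Write the config snapshot (and manifests) that make a run reproducible."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(json.dumps(config, indent=2, default=str))
    if manifests:
        (out / "manifest.json").write_text(json.dumps(manifests, indent=2))
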