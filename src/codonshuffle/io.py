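"""FASTA / GenBank input, ORF concatemers, and table export."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .genetic_code import GeneticCode, standard_code
from .sequence import CodingSequence, SequenceError, translate_cds

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RecordFailure:
    id: str
    reason: str


@dataclass(frozen=True)
class FastaReadResult:
    """Valid coding sequences plus a per-record failure report."""

    sequences: list[CodingSequence]
    failures: list[RecordFailure]

    @property
    def n_records(self) -> int:
        return len(self.sequences) + len(self.failures)


def read_cds_fasta(
    path: str | Path,
    code: GeneticCode | None = None,
    ambiguous: str = "reject",
) -> FastaReadResult:
    """Read in-frame coding sequences from FASTA, validating each record.

    Records that fail validation (frame errors, internal stops, bad
    characters) are reported with their reason instead of aborting the read.
    """
    path = Path(path)
    if code is None:
        code = standard_code()
    sequences: list[CodingSequence] = []
    failures: list[RecordFailure] = []
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        try:
            sequences.append(
                translate_cds(str(rec.seq), code=code, id=rec.id, ambiguous=ambiguous)
            )
        except SequenceError as exc:
            failures.append(RecordFailure(rec.id, str(exc)))
    if n == 0:
        raise ValueError(f"{path}: no FASTA records found")
    return FastaReadResult(sequences, failures)


def write_cds_fasta(seqs: Iterable[CodingSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.nt), width):
                fh.write(s.nt[i : i + width] + "\n")


def read_genbank(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "genbank"))


@dataclass(frozen=True)
class ConcatemerRecipe:
    """Which CDS features, from which records, to join in frame.

    ``sources`` is an ordered list of ``(record_id, selectors)`` where each
    selector is ``"all"``, a 0-based CDS index, or a string matched against
    the feature's gene / locus_tag / product / protein_id qualifiers.  With
    ``exclude_overlaps`` set, genomic regions covered by two or more CDS
    features are excised codon-wise (whole codons of the selected CDS that
    touch an overlap are dropped, keeping the frame).  ``expected_length``
    validates the final concatemer length in nucleotides.
    """

    sources: tuple[tuple[str, tuple[object, ...]], ...]
    exclude_overlaps: bool = False
    expected_length: int | None = None


class ConcatemerError(ValueError):
    pass


def _record_matches(rec: SeqRecord, rid: str) -> bool:
    names = {rec.id, rec.name, rec.id.split(".")[0]}
    return rid in names


def _feature_label(feat) -> str:
    for key in ("gene", "locus_tag", "product", "protein_id"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return str(feat.location)


def _selector_matches(feat, selector) -> bool:
    values = []
    for key in ("gene", "locus_tag", "product", "protein_id"):
        values.extend(feat.qualifiers.get(key, []))
    return any(selector == v for v in values)


def _extracted_positions(feat) -> list[int]:
    """Genomic coordinates of the extracted bases, in extraction order."""
    positions: list[int] = []
    for part in feat.location.parts:
        ps = list(range(int(part.start), int(part.end)))
        if part.strand == -1:
            ps.reverse()
        positions.extend(ps)
    return positions


def _overlap_positions(record: SeqRecord) -> set[int]:
    """Genomic positions covered by two or more CDS features."""
    from collections import Counter

    cover: Counter = Counter()
    for feat in record.features:
        if feat.type != "CDS":
            continue
        for part in feat.location.parts:
            for p in range(int(part.start), int(part.end)):
                cover[p] += 1
    return {p for p, k in cover.items() if k >= 2}


def build_concatemer(
    recipe: ConcatemerRecipe,
    records: Sequence[SeqRecord],
    code: GeneticCode | None = None,
    id: str = "concatemer",
) -> CodingSequence:
    """Extract, trim and join CDS features into one in-frame analysis unit.

    Each extracted CDS is stripped of its terminal stop codon; junctions
    between segments are then treated as ordinary codon boundaries by all
    downstream statistics.
    """
    if code is None:
        code = standard_code()
    pieces: list[str] = []
    for rid, selectors in recipe.sources:
        rec = next((r for r in records if _record_matches(r, rid)), None)
        if rec is None:
            raise ConcatemerError(f"record {rid!r} not found among inputs")
        cds_feats = [f for f in rec.features if f.type == "CDS"]
        if not cds_feats:
            raise ConcatemerError(f"record {rid!r} has no CDS features")
        selected = []
        for sel in selectors:
            if sel == "all":
                selected.extend(cds_feats)
            elif isinstance(sel, int):
                if sel >= len(cds_feats):
                    raise ConcatemerError(f"record {rid!r}: no CDS with index {sel}")
                selected.append(cds_feats[sel])
            else:
                matches = [f for f in cds_feats if _selector_matches(f, sel)]
                if not matches:
                    raise ConcatemerError(f"record {rid!r}: no CDS matching {sel!r}")
                selected.extend(matches)
        overlaps = _overlap_positions(rec) if recipe.exclude_overlaps else set()
        for feat in selected:
            seq = str(feat.extract(rec.seq)).upper().replace("U", "T")
            if len(seq) % 3 != 0:
                raise ConcatemerError(
                    f"record {rid!r}, CDS {_feature_label(feat)!r}: "
                    f"extracted length {len(seq)} is out of frame"
                )
            if overlaps:
                pos = _extracted_positions(feat)
                kept = []
                dropped = 0
                for i in range(0, len(seq), 3):
                    if any(p in overlaps for p in pos[i : i + 3]):
                        dropped += 1
                    else:
                        kept.append(seq[i : i + 3])
                if dropped:
                    logger.info(
                        "%s/%s: excised %d codon(s) overlapping another frame",
                        rid, _feature_label(feat), dropped,
                    )
                seq = "".join(kept)
            if len(seq) >= 3 and code.codon_to_aa[seq[-3:]] == "*":
                seq = seq[:-3]
            pieces.append(seq)
    concat = "".join(pieces)
    try:
        cds = translate_cds(concat, code=code, id=id)
    except SequenceError as exc:
        raise ConcatemerError(f"concatemer invalid: {exc}") from exc
    if recipe.expected_length is not None and len(cds.nt) != recipe.expected_length:
        raise ConcatemerError(
            f"concatemer length {len(cds.nt)} != expected {recipe.expected_length}"
        )
    return cds
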