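"""Read recovery, translation and helix-level filtering of B1H selections.

The raw product of a selection is a pool of deep-sequencing reads.  Each read
carries a selection barcode and a 21-nt insert coding the seven helix
residues (six designable positions plus the invariant +4 leucine).  The
pipeline here is: demultiplex and trim reads into per-selection 21-mer
tables, translate them into core helices aggregating synonymous encodings,
then filter helices on read support and encoding diversity -- helices coded
by a single DNA or seen in a single read are indistinguishable from
sequencing artefacts and selection escapees.
"""

from __future__ import annotations

import gzip
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from zfhelix.synthetic import nns_codons
from zfhelix.types import (
    BASES,
    CoreHelix,
    DnaTarget,
    HelixPair,
    InputError,
    LibraryContext,
    SelectionDataset,
    SelectionRecord,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Demultiplexing and translation
# ---------------------------------------------------------------------------


def demultiplex_and_trim(
    reads,
    barcode_map: Mapping[str, str],
    insert_offset: int = 0,
    insert_length: int = 21,
) -> tuple[dict[str, dict[str, int]], dict[str, int]]:
    """Assign reads to selections by 5' barcode and trim out the insert.

    Parameters
    ----------
    reads
        A path to a FASTQ file (gzip-aware) or an iterable of read strings.
    barcode_map
        Barcode sequence -> selection id.  Barcodes must share one length.
    insert_offset
        Fixed offset from the end of the barcode to the start of the insert.

    Returns
    -------
    tables, log
        ``tables[selection_id]`` maps each trimmed ``insert_length``-mer to
        its read count; ``log`` counts assigned / unassigned / rejected
        reads (rejected = too short or non-ACGT insert).
    """
    if not barcode_map:
        raise InputError("barcode_map must not be empty")
    lengths = {len(b) for b in barcode_map}
    if len(lengths) != 1:
        raise InputError("all barcodes must have the same length")
    blen = lengths.pop()

    tables: dict[str, dict[str, int]] = {sid: {} for sid in barcode_map.values()}
    log = {"total": 0, "assigned": 0, "unassigned": 0, "rejected": 0}
    for read in _iter_read_strings(reads):
        log["total"] += 1
        barcode = read[:blen]
        sid = barcode_map.get(barcode)
        if sid is None:
            log["unassigned"] += 1
            continue
        start = blen + insert_offset
        insert = read[start : start + insert_length]
        if len(insert) < insert_length or set(insert) - set(BASES):
            log["rejected"] += 1
            continue
        log["assigned"] += 1
        table = tables[sid]
        table[insert] = table.get(insert, 0) + 1
    return tables, log


def _iter_read_strings(reads) -> Iterable[str]:
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as handle:
            for rec in SeqIO.parse(handle, "fastq"):
                yield str(rec.seq).upper()
    else:
        for read in reads:
            yield str(read).upper()


def translate_helices(table: Mapping[str, int]) -> list[SelectionRecord]:
    """Translate a table of 21-mer (or 42-mer, for pairs) DNA counts into
    helix records, aggregating synonymous encodings.

    The 5th residue of each translated 7-mer (helix position +4, the
    invariant leucine) is dropped.  In-frame stops and non-ACGT symbols
    reject the encoding; NNS violations (third codon base A/T) are logged as
    warnings only, since sequencing error can produce them.
    """
    grouped: dict[str, dict[str, int]] = {}
    n_rejected = 0
    for dna, count in table.items():
        dna = dna.upper()
        if len(dna) not in (21, 42) or len(dna) % 3:
            raise InputError(f"encoding length {len(dna)} is not 21 or 42: {dna!r}")
        if set(dna) - set(BASES):
            n_rejected += 1
            continue
        protein = str(Seq(dna).translate())
        if "*" in protein:
            n_rejected += 1
            continue
        for k in range(0, len(dna), 3):
            if dna[k + 2] not in "GC":
                logger.warning("non-NNS codon %s in %s", dna[k : k + 3], dna)
        helix = "".join(
            protein[i] for i in range(len(protein)) if i % 7 != 4
        )
        grouped.setdefault(helix, {})[dna] = grouped.get(helix, {}).get(dna, 0) + count
    if n_rejected:
        logger.info("rejected %d encodings (stops or bad symbols)", n_rejected)
    records = []
    for helix, encodings in sorted(grouped.items()):
        obj = HelixPair.from_string(helix) if len(helix) == 12 else CoreHelix(helix)
        records.append(SelectionRecord(helix_or_pair=obj, encoding_counts=encodings))
    return records


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def basic_filter(records: Iterable[SelectionRecord]) -> list[SelectionRecord]:
    """Keep helices with at least two reads that were coded by at least two
    different DNAs."""
    return [r for r in records if r.total_reads >= 2 and r.n_encodings >= 2]


def n_possible_encodings(record: SelectionRecord) -> int:
    """Number of NNS-consistent DNA encodings of a helix (leucine included)."""
    fingers = (
        [record.sequence[:6], record.sequence[6:]]
        if len(record.sequence) == 12
        else [record.sequence]
    )
    n = 1
    for finger in fingers:
        for aa in finger[:4] + "L" + finger[4:]:
            n *= len(nns_codons(aa))
    return n


def encoding_entropy(record: SelectionRecord, normalized: bool = True) -> float:
    """Shannon entropy (bits) of the read distribution over encodings.

    With ``normalized=True`` (default) the entropy is divided by log2 of the
    number of possible NNS encodings of the helix, giving a [0, 1] statistic
    comparable across helices with different codon degeneracy.
    """
    counts = [c for c in record.encoding_counts.values() if c > 0]
    total = sum(counts)
    if total == 0:
        return 0.0
    h = -sum((c / total) * math.log2(c / total) for c in counts)
    if normalized:
        denom = math.log2(n_possible_encodings(record))
        h = h / denom if denom > 0 else 0.0
    return h


def entropy_filter(
    records: Iterable[SelectionRecord],
    min_reads: int = 10,
    min_entropy: float = 0.07,
    normalized: bool = True,
) -> list[SelectionRecord]:
    """Keep helices with at least ``min_reads`` reads and encoding-read
    Shannon entropy of at least ``min_entropy`` -- the stricter filter used
    to assemble model training data."""
    return [
        r
        for r in records
        if r.total_reads >= min_reads
        and encoding_entropy(r, normalized=normalized) >= min_entropy
    ]


# ---------------------------------------------------------------------------
# Dataset readers / writers
# ---------------------------------------------------------------------------

_COLUMNS = ["helix", "encoding_dna", "reads"]


def write_dataset(dataset: SelectionDataset, path: str | Path) -> None:
    """Write a selection as a TSV (helix, encoding_dna, reads) plus a JSON
    manifest alongside it."""
    path = Path(path)
    rows = []
    for rec in dataset.records:
        for enc, count in sorted(rec.encoding_counts.items()):
            rows.append((rec.sequence, enc, count))
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)
    manifest = {
        "target": str(dataset.target),
        "library_id": dataset.library_id,
        "metadata": dataset.metadata,
    }
    if dataset.context is not None:
        manifest["context"] = {
            "library_id": dataset.context.library_id,
            "fixed_helices": [str(h) for h in dataset.context.fixed_helices],
            "overlap_base": dataset.context.overlap_base,
        }
    Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=2))


def read_dataset(path: str | Path) -> SelectionDataset:
    """Read a selection written by :func:`write_dataset`.

    Malformed or duplicated rows raise :class:`InputError` naming the line.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"helix": str, "encoding_dna": str})
    if list(df.columns) != _COLUMNS:
        raise InputError(f"{path}: expected columns {_COLUMNS}, got {list(df.columns)}")
    grouped: dict[str, dict[str, int]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        helix, enc, reads = row
        if not isinstance(helix, str) or not isinstance(enc, str):
            raise InputError(f"{path}: malformed row at line {i}")
        try:
            reads = int(reads)
        except (TypeError, ValueError):
            raise InputError(f"{path}: non-integer read count at line {i}") from None
        if reads < 0:
            raise InputError(f"{path}: negative read count at line {i}")
        encs = grouped.setdefault(helix, {})
        if enc in encs:
            raise InputError(f"{path}: duplicated helix/encoding row at line {i}")
        encs[enc] = reads

    manifest_path = Path(str(path) + ".manifest.json")
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    records = []
    for helix, encodings in grouped.items():
        obj = HelixPair.from_string(helix) if len(helix) == 12 else CoreHelix(helix)
        records.append(SelectionRecord(helix_or_pair=obj, encoding_counts=encodings))
    context = None
    if "context" in manifest:
        c = manifest["context"]
        context = LibraryContext(
            library_id=c["library_id"],
            fixed_helices=tuple(CoreHelix(h) for h in c["fixed_helices"]),
            overlap_base=c["overlap_base"],
        )
    target = DnaTarget(manifest.get("target") or _infer_target(records))
    return SelectionDataset(
        target=target,
        records=records,
        context=context,
        library_id=manifest.get("library_id"),
        metadata=manifest.get("metadata", {}),
    )


def _infer_target(records: list[SelectionRecord]) -> str:
    if records and len(records[0].sequence) == 12:
        return "A" * 7
    return "A" * 4
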