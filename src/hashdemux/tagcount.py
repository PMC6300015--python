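"""Tag quantification: raw paired reads → barcode × tag UMI count matrix.

Read 1 carries the cell barcode and UMI (10x 3' v2 layout: 16 bp + 10 bp by
default); read 2 carries the tag sequence. Each observed tag is assigned to
the unique library barcode within a maximum hamming distance (default 1,
ties discarded), and one UMI is counted per distinct
(cell barcode, UMI, tag) triple.
"""

from __future__ import annotations

import csv
import gzip
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .matrix import TagCountMatrix

__all__ = [
    "TagLibrary",
    "ReadLayout",
    "match_tag",
    "count_tags",
    "count_tags_fastq",
    "hamming",
]


def hamming(a: str, b: str) -> int:
    """Hamming distance; case-insensitive; any N counts as a mismatch."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    return sum(x != y or x == "N" or y == "N" for x, y in zip(a, b))


@dataclass(frozen=True)
class TagLibrary:
    """Named panel of tag barcode sequences (HTO or ADT library).

    All barcodes must share one length. At load time the panel is checked
    for pairwise separation: if any two barcodes are within 2·max_hamming of
    each other, some observed sequences are unavoidably ambiguous and a
    warning is raised.
    """

    names: tuple
    sequences: tuple

    def __post_init__(self):
        if len(self.names) == 0:
            raise ValueError("empty tag library")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate tag names in library")
        seqs = tuple(s.upper() for s in self.sequences)
        object.__setattr__(self, "sequences", seqs)
        if len(set(len(s) for s in seqs)) != 1:
            raise ValueError("all tag barcodes must have the same length")
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate tag barcode sequences in library")

    @property
    def barcode_length(self) -> int:
        return len(self.sequences[0])

    def min_pairwise_distance(self) -> int:
        seqs = self.sequences
        if len(seqs) == 1:
            return self.barcode_length
        return min(
            hamming(seqs[i], seqs[j])
            for i in range(len(seqs))
            for j in range(i + 1, len(seqs))
        )

    def validate_separation(self, max_hamming: int) -> None:
        d = self.min_pairwise_distance()
        if d <= 2 * max_hamming:
            warnings.warn(
                f"tag barcodes are only {d} mismatches apart; with "
                f"max_hamming={max_hamming} some observed sequences are "
                "unavoidably ambiguous and will be discarded",
                UserWarning,
                stacklevel=2,
            )

    @classmethod
    def from_csv(cls, path, max_hamming: int = 1) -> "TagLibrary":
        """Load a 2-column CSV (name,sequence); a header row is optional."""
        names, seqs = [], []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) < 2:
                    raise ValueError(f"{path}: expected 2 columns, got {row!r}")
                name, seq = row[0].strip(), row[1].strip()
                if name.lower() in {"name", "sample"} and not set(seq.upper()) <= set("ACGTN"):
                    continue  # header row
                names.append(name)
                seqs.append(seq)
        lib = cls(tuple(names), tuple(seqs))
        lib.validate_separation(max_hamming)
        return lib


@dataclass(frozen=True)
class ReadLayout:
    """(start, length) spans of cell barcode and UMI on read 1, tag on read 2.

    Defaults match the 10x Genomics 3' v2 chemistry with a 12-bp hashtag:
    16-bp cell barcode, 10-bp UMI.
    """

    cell_barcode_span: tuple = (0, 16)
    umi_span: tuple = (16, 10)
    tag_span: tuple = (0, 12)

    def __post_init__(self):
        for span in (self.cell_barcode_span, self.umi_span, self.tag_span):
            if len(span) != 2 or span[0] < 0 or span[1] <= 0:
                raise ValueError(f"invalid span {span}: need (start>=0, length>0)")
        a, b = sorted([self.cell_barcode_span, self.umi_span])
        if a[0] + a[1] > b[0]:
            raise ValueError("cell barcode and UMI spans overlap on read 1")

    @property
    def min_r1_length(self) -> int:
        return max(s + l for s, l in (self.cell_barcode_span, self.umi_span))

    @property
    def min_r2_length(self) -> int:
        return self.tag_span[0] + self.tag_span[1]


def match_tag(observed: str, library: TagLibrary, max_hamming: int = 1):
    """Assign an observed tag sequence to a library entry.

    Returns the sample name of the unique entry within ``max_hamming``
    mismatches, or ``None`` (no match) if none qualifies or if two or more
    entries tie at the minimal distance.
    """
    if max_hamming < 0:
        raise ValueError("max_hamming must be >= 0")
    if len(observed) != library.barcode_length:
        raise ValueError(
            f"observed tag length {len(observed)} != library barcode "
            f"length {library.barcode_length}"
        )
    dists = [hamming(observed, s) for s in library.sequences]
    d = min(dists)
    if d > max_hamming or dists.count(d) > 1:
        return None
    return library.names[dists.index(d)]


def count_tags(
    read_pairs,
    layout: ReadLayout,
    library: TagLibrary,
    max_hamming: int = 1,
    barcode_whitelist=None,
) -> tuple[TagCountMatrix, dict]:
    """Count tag UMIs from an iterable of (read1_seq, read2_seq) pairs.

    One UMI is counted per distinct (cell barcode, UMI, assigned tag)
    triple; additional reads of a triple are tallied as duplicates. Pairs
    whose tag has no unique match, whose cell barcode is off-whitelist, or
    whose reads are shorter than the layout requires are dropped and
    tallied in the summary.

    Returns
    -------
    (TagCountMatrix, summary dict). Summary keys: ``total_pairs``,
    ``counted_umis``, ``duplicate_reads``, ``dropped_no_match``,
    ``dropped_off_whitelist``, ``dropped_short_read``.
    """
    if barcode_whitelist is not None:
        barcode_whitelist = set(barcode_whitelist)
    cb_s, cb_l = layout.cell_barcode_span
    umi_s, umi_l = layout.umi_span
    tag_s, tag_l = layout.tag_span
    if tag_l != library.barcode_length:
        raise ValueError(
            f"layout tag span length {tag_l} != library barcode length "
            f"{library.barcode_length}"
        )

    seen: set = set()
    tag_index = {n: i for i, n in enumerate(library.names)}
    counts: dict = {}
    summary = {
        "total_pairs": 0,
        "counted_umis": 0,
        "duplicate_reads": 0,
        "dropped_no_match": 0,
        "dropped_off_whitelist": 0,
        "dropped_short_read": 0,
    }
    for r1, r2 in read_pairs:
        summary["total_pairs"] += 1
        if len(r1) < layout.min_r1_length or len(r2) < layout.min_r2_length:
            summary["dropped_short_read"] += 1
            continue
        cell = r1[cb_s : cb_s + cb_l].upper()
        if barcode_whitelist is not None and cell not in barcode_whitelist:
            summary["dropped_off_whitelist"] += 1
            continue
        tag = match_tag(r2[tag_s : tag_s + tag_l], library, max_hamming)
        if tag is None:
            summary["dropped_no_match"] += 1
            continue
        umi = r1[umi_s : umi_s + umi_l].upper()
        triple = (cell, umi, tag)
        if triple in seen:
            summary["duplicate_reads"] += 1
            continue
        seen.add(triple)
        key = (cell, tag_index[tag])
        counts[key] = counts.get(key, 0) + 1
        summary["counted_umis"] += 1

    barcodes = sorted({cell for cell, _ in counts})
    row = {b: i for i, b in enumerate(barcodes)}
    if counts:
        rows = [row[c] for c, _ in counts]
        cols = [t for _, t in counts]
        data = list(counts.values())
        X = sparse.coo_matrix(
            (data, (rows, cols)), shape=(len(barcodes), len(library.names)),
            dtype=np.int64,
        )
    else:
        X = sparse.coo_matrix((0, len(library.names)), dtype=np.int64)
    return TagCountMatrix(X, barcodes, list(library.names)), summary


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _fastq_pairs(r1_path, r2_path):
    """Yield (seq1, seq2) from paired FASTQ files, validating record sync."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_maybe_gzip(r1_path) as f1, _open_maybe_gzip(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        n = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            n += 1
            if rec1 is None or rec2 is None:
                short = r1_path if rec1 is None else r2_path
                raise ValueError(
                    f"{short}: ran out of reads at record {n}; paired FASTQ "
                    "files have unequal record counts"
                )
            yield rec1[1], rec2[1]


def count_tags_fastq(
    r1_path,
    r2_path,
    library: TagLibrary,
    layout: ReadLayout = ReadLayout(),
    max_hamming: int = 1,
    barcode_whitelist=None,
) -> tuple[TagCountMatrix, dict]:
    """Count tag UMIs from paired FASTQ files (plain or gzipped)."""
    try:
        return count_tags(
            _fastq_pairs(r1_path, r2_path), layout, library, max_hamming,
            barcode_whitelist,
        )
    except ValueError as e:
        if "FASTQ" in str(e) or "Fastq" in str(e) or "@" in str(e):
            raise ValueError(f"malformed FASTQ in {r1_path}/{r2_path}: {e}") from e
        raise
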