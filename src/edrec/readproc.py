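"""Read processing for targeted recorder amplicon sequencing.

The processing core mirrors a simple string pipeline: reads are
assigned to library members by exact barcode match, checked against the
invariant sequences flanking the adenosine-rich recorder region, the
recorder / variable-region / UMI fields are extracted at the annotated
coordinates, PCR duplicates are collapsed by keeping the first
occurrence of each UMI per barcode, and per-adenosine base counts plus
a per-read edit-count histogram are tallied for every unique variable
region (or, for deep-mutational-scanning libraries, every barcode).

An "edit" is a G read at a designed adenosine offset: A-to-I editing
is read out as an A→G substitution after reverse transcription.  C or
T reads at designed sites are tallied but treated as sequencing error,
and the efficiency denominator is the total number of deduplicated
reads.

Conservation counters are exposed at every stage:
``reads_in = assigned + unassigned``;
``assigned = passed_filter + failed_filter``;
``passed_filter = deduped_kept + dedup_dropped``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import SequenceParts

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: designed adenosine offsets of the default recorder
DEFAULT_A_OFFSETS = SequenceParts().recorder_a_offsets


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    with _open_maybe_gzip(path) as fh:
        yield from FastqGeneralIterator(fh)


@dataclass
class ProcessedRead:
    """A read that survived barcode assignment and flank filtering."""

    barcode: str
    umi: str
    recorder_seq: str
    variable_seq: str


@dataclass
class EditTally:
    """UMI-deduplicated editing tally for one library variant.

    ``base_counts`` is an (n_sites, 4) matrix of A/C/G/T counts over
    the designed adenosine offsets; ``edit_histogram`` counts reads
    with 0..n_sites G calls at those offsets.  Each row of
    ``base_counts`` and the histogram both sum to ``umi_count``.
    """

    variant_key: str
    refa_offsets: tuple[int, ...]
    umi_count: int = 0
    base_counts: np.ndarray = None
    edit_histogram: np.ndarray = None
    design_class: str = ""

    def __post_init__(self):
        n = len(self.refa_offsets)
        if self.base_counts is None:
            self.base_counts = np.zeros((n, 4), dtype=np.int64)
        if self.edit_histogram is None:
            self.edit_histogram = np.zeros(n + 1, dtype=np.int64)

    def add_read(self, recorder_seq: str) -> None:
        n_edits = 0
        for i, off in enumerate(self.refa_offsets):
            base = recorder_seq[off] if off < len(recorder_seq) else "N"
            if base in _BASE_INDEX:
                self.base_counts[i, _BASE_INDEX[base]] += 1
                if base == "G":
                    n_edits += 1
            else:
                # ambiguous call counts toward the denominator as non-edit A
                self.base_counts[i, _BASE_INDEX["A"]] += 1
        self.edit_histogram[n_edits] += 1
        self.umi_count += 1

    def merge(self, other: "EditTally") -> None:
        if other.refa_offsets != self.refa_offsets:
            raise ValueError("cannot merge tallies with different site offsets")
        self.umi_count += other.umi_count
        self.base_counts += other.base_counts
        self.edit_histogram += other.edit_histogram


# ---------------------------------------------------------------------------
# stage operations
# ---------------------------------------------------------------------------


def split_by_barcode(
    read1_fastq,
    read2_fastq,
    annotations: pd.DataFrame,
) -> tuple[dict[str, list[tuple[str, str]]], dict]:
    """Assign read pairs to barcodes by exact match at the read start.

    Returns ``(streams, counters)`` where ``streams`` maps each
    annotated barcode to its ``(read1, umi)`` pairs plus an
    ``"unassigned"`` bucket.  Barcode lengths may differ between
    library classes; longer barcodes take precedence.
    """
    barcodes = set(annotations["barcode"])
    if len(barcodes) != len(annotations):
        raise ValueError("annotation barcodes are not unique")
    lengths = sorted({len(b) for b in barcodes}, reverse=True)
    streams: dict[str, list[tuple[str, str]]] = {b: [] for b in barcodes}
    streams["unassigned"] = []
    counters = {"reads_in": 0, "assigned": 0, "unassigned": 0}
    r1_iter = iter_fastq(read1_fastq)
    r2_iter = iter_fastq(read2_fastq)
    for (id1, seq1, _q1), (id2, seq2, _q2) in zip(r1_iter, r2_iter):
        if id1.split()[0] != id2.split()[0]:
            raise ValueError(f"read pairing mismatch: {id1!r} vs {id2!r}")
        counters["reads_in"] += 1
        for length in lengths:
            prefix = seq1[:length]
            if prefix in barcodes:
                streams[prefix].append((seq1, seq2))
                counters["assigned"] += 1
                break
        else:
            streams["unassigned"].append((seq1, seq2))
            counters["unassigned"] += 1
    # guard against extra reads in either file
    for leftover in (r1_iter, r2_iter):
        if next(leftover, None) is not None:
            raise ValueError("Read-1 and Read-2 files have different lengths")
    return streams, counters


def filter_invariant_flanks(read1: str, annotation: pd.Series) -> bool:
    """True iff both invariant recorder flanks match at their offsets."""
    rs = int(annotation["recorder_start"])
    rl = int(annotation["recorder_length"])
    up = annotation["upstream_flank"] or ""
    down = annotation["downstream_flank"] or ""
    if read1[max(rs - len(up), 0) : rs] != up:
        return False
    if read1[rs + rl : rs + rl + len(down)] != down:
        return False
    return True


def dedup_umi(reads: Iterable[ProcessedRead]) -> Iterator[ProcessedRead]:
    """Keep only the first occurrence of each UMI, in input order."""
    seen: set[str] = set()
    for read in reads:
        if read.umi in seen:
            continue
        seen.add(read.umi)
        yield read


def extract_read(read1: str, umi: str, annotation: pd.Series) -> ProcessedRead | None:
    """Extract recorder/variable fields; None if the read is too short."""
    rs = int(annotation["recorder_start"])
    rl = int(annotation["recorder_length"])
    vs = int(annotation["insert_start"])
    vl = int(annotation["insert_length"])
    if len(read1) < max(rs + rl, vs + vl):
        return None
    return ProcessedRead(
        barcode=annotation["barcode"],
        umi=umi,
        recorder_seq=read1[rs : rs + rl],
        variable_seq=read1[vs : vs + vl],
    )


def tally_edits(
    reads: Iterable[ProcessedRead],
    annotation: pd.Series,
    a_offsets: tuple[int, ...] = DEFAULT_A_OFFSETS,
    tallies: dict[str, EditTally] | None = None,
) -> dict[str, EditTally]:
    """Tally deduplicated reads into per-variant editing counts.

    The variant key is the barcode for DMS libraries and the extracted
    variable-region sequence otherwise.
    """
    if tallies is None:
        tallies = {}
    is_dms = annotation["design_class"] == "dms"
    for read in reads:
        key = read.barcode if is_dms else read.variable_seq
        tally = tallies.get(key)
        if tally is None:
            tally = EditTally(
                variant_key=key,
                refa_offsets=tuple(a_offsets),
                design_class=annotation["design_class"],
            )
            tallies[key] = tally
        tally.add_read(read.recorder_seq)
    return tallies


def process_reads(
    read1_fastq,
    read2_fastq,
    annotations: pd.DataFrame,
    a_offsets: tuple[int, ...] = DEFAULT_A_OFFSETS,
) -> tuple[dict[str, EditTally], dict]:
    """Full pipeline: split, flank-filter, extract, dedup, tally."""
    streams, counters = split_by_barcode(read1_fastq, read2_fastq, annotations)
    counters.update(
        passed_filter=0, failed_filter=0, deduped_kept=0, dedup_dropped=0,
        too_short=0,
    )
    ann_by_barcode = {row["barcode"]: row for _, row in annotations.iterrows()}
    tallies: dict[str, EditTally] = {}
    for barcode, pairs in streams.items():
        if barcode == "unassigned":
            continue
        ann = ann_by_barcode[barcode]
        passed: list[ProcessedRead] = []
        for read1, umi in pairs:
            if not filter_invariant_flanks(read1, ann):
                counters["failed_filter"] += 1
                continue
            extracted = extract_read(read1, umi, ann)
            if extracted is None:
                counters["too_short"] += 1
                counters["failed_filter"] += 1
                continue
            counters["passed_filter"] += 1
            passed.append(extracted)
        deduped = list(dedup_umi(passed))
        counters["deduped_kept"] += len(deduped)
        counters["dedup_dropped"] += len(passed) - len(deduped)
        tally_edits(deduped, ann, a_offsets=a_offsets, tallies=tallies)
    return tallies, counters


# ---------------------------------------------------------------------------
# tally serialization
# ---------------------------------------------------------------------------


def tallies_to_frames(tallies: dict[str, EditTally]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format per-site counts and per-read edit histogram tables."""
    site_rows, hist_rows = [], []
    for key in sorted(tallies):
        t = tallies[key]
        for i, off in enumerate(t.refa_offsets):
            site_rows.append(
                {
                    "variant_key": key,
                    "umi_count": t.umi_count,
                    "site_index": i,
                    "refA_offset": off,
                    "count_A": int(t.base_counts[i, 0]),
                    "count_C": int(t.base_counts[i, 1]),
                    "count_G": int(t.base_counts[i, 2]),
                    "count_T": int(t.base_counts[i, 3]),
                }
            )
        for n_edits, reads in enumerate(t.edit_histogram):
            hist_rows.append(
                {"variant_key": key, "n_edits": n_edits, "reads": int(reads)}
            )
    return pd.DataFrame(site_rows), pd.DataFrame(hist_rows)


def frames_to_tallies(
    site_frame: pd.DataFrame, hist_frame: pd.DataFrame
) -> dict[str, EditTally]:
    tallies: dict[str, EditTally] = {}
    for key, grp in site_frame.groupby("variant_key", sort=True):
        grp = grp.sort_values("site_index")
        offsets = tuple(int(o) for o in grp["refA_offset"])
        counts = grp[["count_A", "count_C", "count_G", "count_T"]].to_numpy(
            dtype=np.int64
        )
        hist = (
            hist_frame[hist_frame["variant_key"] == key]
            .sort_values("n_edits")["reads"]
            .to_numpy(dtype=np.int64)
        )
        tallies[str(key)] = EditTally(
            variant_key=str(key),
            refa_offsets=offsets,
            umi_count=int(grp["umi_count"].iloc[0]),
            base_counts=counts,
            edit_histogram=hist,
        )
    return tallies


# ---------------------------------------------------------------------------
# long-read scoring
# ---------------------------------------------------------------------------

LONGREAD_WINDOW = 40


@dataclass
class LongReadResult:
    """Per-population editing efficiency from the low-throughput assay."""

    population: str  # "boxb" or "no_boxb"
    n_reads: int
    n_kept: int
    n_discarded_indel: int
    edited_a: int
    total_a: int
    reads_ge1: int

    @property
    def efficiency(self) -> float | None:
        return self.edited_a / self.total_a if self.total_a else None

    @property
    def frac_reads_ge1(self) -> float | None:
        return self.reads_ge1 / self.n_kept if self.n_kept else None


def _divergence_point(ref_with: str, ref_without: str) -> int:
    for i, (a, b) in enumerate(zip(ref_with, ref_without)):
        if a != b:
            return i
    return min(len(ref_with), len(ref_without))


def score_longreads(
    fastq,
    reference_with_boxb: str,
    reference_without_boxb: str,
    motif: str | None = None,
) -> dict[str, LongReadResult]:
    """Score full-length reporter reads from the low-throughput assay.

    Reads are sorted into boxB-containing and boxB-lacking populations
    by presence of the boxB motif.  Within the 40-nt window immediately
    3' of the insertion site, A→G substitutions are counted against the
    population's reference; reads whose length differs from the
    reference (implying an insertion or deletion) are discarded.
    """
    from .design import BOXB_MOTIF

    motif = motif or BOXB_MOTIF
    ins = _divergence_point(reference_with_boxb, reference_without_boxb)
    insert_len = len(reference_with_boxb) - len(reference_without_boxb)
    if insert_len <= 0:
        raise ValueError("reference_with_boxb must be longer than the control")
    windows = {
        "boxb": (reference_with_boxb, ins + insert_len),
        "no_boxb": (reference_without_boxb, ins),
    }
    results = {
        pop: LongReadResult(pop, 0, 0, 0, 0, 0, 0) for pop in windows
    }
    if isinstance(fastq, (str, bytes)) or hasattr(fastq, "__fspath__"):
        reads = ((name, seq) for name, seq, _q in iter_fastq(fastq))
    else:
        reads = iter(fastq)
    for _name, seq in reads:
        pop = "boxb" if motif in seq else "no_boxb"
        ref, wstart = windows[pop]
        res = results[pop]
        res.n_reads += 1
        if len(seq) != len(ref) or wstart + LONGREAD_WINDOW > len(seq):
            res.n_discarded_indel += 1
            continue
        ref_win = ref[wstart : wstart + LONGREAD_WINDOW]
        read_win = seq[wstart : wstart + LONGREAD_WINDOW]
        edits = sum(1 for r, s in zip(ref_win, read_win) if r == "A" and s == "G")
        n_a = ref_win.count("A")
        res.n_kept += 1
        res.edited_a += edits
        res.total_a += n_a
        if edits >= 1:
            res.reads_ge1 += 1
    return results
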