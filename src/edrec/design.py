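"""Oligo-pool design for RNA-recording reporter libraries.

An RNA-recording reporter couples an adenosine-rich "recorder" segment
(whose A-to-I editing level reports recruitment of a deaminase) to a
boxB stem loop (the RNA element bound by the λN peptide that recruits
the enzyme).  This module designs the four pooled libraries used to
dissect that system:

* ``spacer``          – the recorder is moved relative to boxB by
                        truncating and splitting an A-depleted spacer;
* ``recorder_random`` – non-A positions of the recorder are randomized
                        in two groups to probe sequence-context bias;
* ``loop_random`` / ``stem_random`` – windows of the 19-nt boxB stem
                        loop are exhaustively randomized;
* ``dms``             – every codon of the λN open reading frame is
                        replaced by NNN, each variant linked to
                        A-depleted barcodes (deep mutational scanning).

Every library member is tagged by a barcode from an A-free code with
pairwise Hamming distance ≥ 2, and the designs are emitted together
with the annotation table that the read processor consumes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

DNA_BASES = "ACGT"

#: length of the first (insert-covering) sequencing read
READ1_LENGTH = 79
#: length of the UMI read
UMI_LENGTH = 7

#: fixed 3' sequence a read runs into when the insert is shorter than Read 1
SEQUENCING_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

#: boxB motif used to classify long reads (loop plus adjacent stem)
BOXB_MOTIF = "GCCCTGAAGAAGGGC"

#: number of flanking bases recorded on each side of the recorder
FLANK_LENGTH = 6


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class SequenceParts:
    """Constant sequence elements of the reporter oligo (DNA sense).

    Defaults are the elements of the reporter used throughout the
    package: T7 promoter, forward PCR handle, a 30-nt A-depleted
    spacer, the 17-nt recorder with 8 adenosines, the 19-nt wild-type
    boxB stem loop and the reverse-transcription handle.
    """

    t7_promoter: str = "TAATACGACTCACTATAGG"
    fwd_handle: str = "TGGCTTCGTTGTTGTGCT"
    spacer: str = "TTTGTGTTCTCTTGTTCGTTCTGGTTCGTT"
    recorder: str = "TAGAATTACACCATAAT"
    boxb_stemloop: str = "GGGCCCTGAAGAAGGGCCC"
    rt_handle: str = "GCTGGCTTCTGTTCCGTTTG"
    barcode_buffer: str = "TCG"

    def __post_init__(self) -> None:
        if len(self.boxb_stemloop) != 19:
            raise ValueError("boxB stem loop must be 19 nt")
        stem5 = self.boxb_stemloop[:6]
        stem3 = self.boxb_stemloop[13:]
        if reverse_complement(stem5) != stem3:
            raise ValueError("stem positions 1-6 must pair with 14-19")
        if "A" not in self.recorder:
            raise ValueError("recorder carries no adenosines to edit")

    @property
    def recorder_a_offsets(self) -> tuple[int, ...]:
        """0-based offsets of the designed adenosines within the recorder."""
        return tuple(i for i, b in enumerate(self.recorder) if b == "A")


@dataclass(frozen=True)
class OligoRecord:
    """One designed library member.

    Coordinates (``recorder_start``, ``variable_start``) are 0-based
    offsets *within the Read-1 window*, which begins at the barcode
    (``read_start`` maps them back onto ``full_sequence``).
    """

    oligo_id: str
    barcode: str
    orientation: str  # "boxb_5prime" | "boxb_3prime"
    full_sequence: str
    read_start: int
    recorder_start: int
    recorder_length: int
    variable_start: int
    variable_length: int
    design_class: str  # spacer | recorder_random | loop_random | stem_random | dms
    upstream_flank: str
    downstream_flank: str
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def read1_template(self) -> str:
        """Error-free Read-1 sequence for this oligo."""
        padded = self.full_sequence + SEQUENCING_ADAPTER
        return padded[self.read_start : self.read_start + READ1_LENGTH]

    @property
    def recorder_seq(self) -> str:
        return self.read1_template[
            self.recorder_start : self.recorder_start + self.recorder_length
        ]

    @property
    def variable_seq(self) -> str:
        return self.read1_template[
            self.variable_start : self.variable_start + self.variable_length
        ]

    @property
    def variant_key(self) -> str:
        """Key under which reads of this oligo are tallied downstream."""
        return self.barcode if self.design_class == "dms" else self.variable_seq


@dataclass(frozen=True)
class BarcodeSet:
    barcodes: tuple[str, ...]
    length: int
    alphabet: frozenset[str]
    min_hamming: int

    def __iter__(self):
        return iter(self.barcodes)

    def __len__(self) -> int:
        return len(self.barcodes)


class BarcodeCapacityError(ValueError):
    """Raised when the requested code cannot be filled."""


def generate_barcodes(
    n: int,
    length: int = 10,
    exclude_base: str | None = "A",
    min_hamming: int = 2,
    seed: int = 0,
) -> BarcodeSet:
    """Sample ``n`` barcodes of ``length`` nt with pairwise Hamming ≥ ``min_hamming``.

    Barcodes exclude ``exclude_base`` entirely (``A`` by default, so an
    A-to-G edit can never corrupt a barcode into another valid one).
    For ``min_hamming == 2`` the code is built by appending a modular
    checksum symbol to random prefixes, which guarantees the distance
    exactly; larger distances fall back to greedy rejection sampling.
    Deterministic given ``seed``.
    """
    if n < 1 or length < 1:
        raise ValueError("n and length must be positive")
    alphabet = [b for b in DNA_BASES if b != exclude_base]
    k = len(alphabet)
    if min_hamming > 1 and length < 2 and n > 1:
        raise BarcodeCapacityError(
            f"length-{length} barcodes cannot reach distance {min_hamming}; "
            f"achievable count is 1"
        )
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    seen: set[str] = set()

    if min_hamming <= 2:
        # checksum construction: codewords with sum(symbols) == 0 mod k
        # are pairwise distance >= 2 (a single substitution breaks the sum)
        capacity = k ** max(length - (min_hamming - 1), 0)
        if n > capacity:
            raise BarcodeCapacityError(
                f"requested {n} barcodes but only {capacity} are achievable "
                f"at length {length}, distance {min_hamming}, alphabet size {k}"
            )
        max_draws = 200 * n + 1000
        for _ in range(max_draws):
            if len(chosen) == n:
                break
            prefix = rng.integers(0, k, size=max(length - 1, 0))
            if min_hamming == 2 and length > 1:
                check = (-int(prefix.sum())) % k
                word = "".join(alphabet[i] for i in prefix) + alphabet[check]
            else:
                sym = rng.integers(0, k, size=length)
                word = "".join(alphabet[i] for i in sym)
            if word not in seen:
                seen.add(word)
                chosen.append(word)
        if len(chosen) < n:  # pragma: no cover - capacity checked above
            raise BarcodeCapacityError(
                f"could only draw {len(chosen)} of {n} requested barcodes"
            )
    else:
        max_draws = 2000 * n + 5000
        for _ in range(max_draws):
            if len(chosen) == n:
                break
            sym = rng.integers(0, k, size=length)
            word = "".join(alphabet[i] for i in sym)
            if word in seen:
                continue
            if all(hamming(word, other) >= min_hamming for other in chosen):
                seen.add(word)
                chosen.append(word)
        if len(chosen) < n:
            raise BarcodeCapacityError(
                f"greedy sampling exhausted after reaching {len(chosen)} of "
                f"{n} barcodes at distance {min_hamming}"
            )
    return BarcodeSet(
        barcodes=tuple(chosen),
        length=length,
        alphabet=frozenset(alphabet),
        min_hamming=min_hamming,
    )


# ---------------------------------------------------------------------------
# oligo assembly
# ---------------------------------------------------------------------------


def _assemble(
    parts: SequenceParts,
    barcode: str,
    segments: list[tuple[str, str]],
    variable_names: set[str],
    orientation: str,
    design_class: str,
    oligo_id: str,
    meta: dict,
) -> OligoRecord:
    """Concatenate named segments downstream of the barcode into a record.

    Layout: t7 - fwd_handle - buffer - barcode - segments... - rt_handle.
    The Read-1 window starts at the barcode; the named ``recorder``
    segment and the contiguous run of ``variable_names`` segments must
    fall inside it.
    """
    head = parts.t7_promoter + parts.fwd_handle + parts.barcode_buffer
    read_start = len(head)
    offsets: dict[str, tuple[int, int]] = {}
    pos = len(barcode)  # read-relative position after the barcode
    body = []
    for name, seq in segments:
        offsets[name] = (pos, len(seq))
        body.append(seq)
        pos += len(seq)
    full = head + barcode + "".join(body) + parts.rt_handle

    rec_start, rec_len = offsets["recorder"]
    if variable_names == {"barcode"}:
        var_start, var_len = 0, len(barcode)
    else:
        spans = sorted(offsets[n] for n in variable_names)
        var_start = spans[0][0]
        var_end = spans[-1][0] + spans[-1][1]
        for (s, l), (s2, _) in zip(spans, spans[1:]):
            if s + l != s2:
                raise ValueError("variable segments must be contiguous")
        var_len = var_end - var_start
    for nm, (s, l) in (("recorder", (rec_start, rec_len)),
                       ("variable region", (var_start, var_len))):
        if s + l > READ1_LENGTH:
            raise ValueError(
                f"{nm} of {oligo_id} extends past the {READ1_LENGTH}-nt Read-1 window"
            )

    read1 = (full + SEQUENCING_ADAPTER)[read_start : read_start + READ1_LENGTH]
    up = read1[max(rec_start - FLANK_LENGTH, 0) : rec_start]
    down = read1[rec_start + rec_len : rec_start + rec_len + FLANK_LENGTH]
    return OligoRecord(
        oligo_id=oligo_id,
        barcode=barcode,
        orientation=orientation,
        full_sequence=full,
        read_start=read_start,
        recorder_start=rec_start,
        recorder_length=rec_len,
        variable_start=var_start,
        variable_length=var_len,
        design_class=design_class,
        upstream_flank=up,
        downstream_flank=down,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# library designs
# ---------------------------------------------------------------------------


def design_spacer_library(
    parts: SequenceParts | None = None,
    step: int = 2,
    max_trunc: int = 30,
    seed: int = 0,
) -> list[OligoRecord]:
    """Spacer-distance library: recorder moved relative to boxB.

    The spacer is truncated in ``step``-nt increments (0 .. ``max_trunc``
    nt removed); for each truncated spacer every split into a 5' and a 3'
    segment (at ``step``-nt granularity) is emitted with the intact
    recorder inserted between the segments, in both boxB orientations.
    The 3'-segment length sets the recorder-to-boxB distance.
    """
    parts = parts or SequenceParts()
    if step < 1:
        raise ValueError("step must be >= 1")
    if step > len(parts.spacer):
        raise ValueError("step exceeds spacer length")
    if max_trunc > len(parts.spacer):
        raise ValueError("max_trunc exceeds spacer length")
    truncations = list(range(0, max_trunc + 1, step))
    n_oligos = sum(
        2 * (((len(parts.spacer) - t) // step) + 1) for t in truncations
    )
    barcodes = generate_barcodes(n_oligos, seed=seed)
    records = []
    bc_iter = iter(barcodes)
    for t in truncations:
        spacer = parts.spacer[: len(parts.spacer) - t]
        for split in range(0, len(spacer) + 1, step):
            s5, s3 = spacer[:split], spacer[split:]
            for orientation in ("boxb_5prime", "boxb_3prime"):
                if orientation == "boxb_3prime":
                    segments = [
                        ("spacer5", s5),
                        ("recorder", parts.recorder),
                        ("spacer3", s3),
                        ("buffer", parts.barcode_buffer),
                        ("boxb", parts.boxb_stemloop),
                    ]
                else:
                    segments = [
                        ("boxb", parts.boxb_stemloop),
                        ("buffer", parts.barcode_buffer),
                        ("spacer5", s5),
                        ("recorder", parts.recorder),
                        ("spacer3", s3),
                    ]
                oid = f"spacer_t{t}_s{split}_{orientation}"
                records.append(
                    _assemble(
                        parts,
                        next(bc_iter),
                        segments,
                        {"spacer5", "recorder", "spacer3"},
                        orientation,
                        "spacer",
                        oid,
                        meta={
                            "truncation": t,
                            "split": split,
                            "boxb_distance": len(s3),
                            "stemloop": parts.boxb_stemloop,
                        },
                    )
                )
    return records


def default_recorder_groups(parts: SequenceParts, group_size: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Two groups of non-A recorder positions to randomize.

    The recorder has 9 non-A positions; with ``group_size=5`` the two
    groups share their middle position so that together they tile all
    non-A positions while each set enumerates 4^5 sequences.
    """
    non_a = [i for i, b in enumerate(parts.recorder) if b != "A"]
    if not non_a:
        raise ValueError("recorder has no non-A positions to randomize")
    if group_size > len(non_a):
        raise ValueError("group_size exceeds number of non-A recorder positions")
    return tuple(non_a[:group_size]), tuple(non_a[-group_size:])


def design_recorder_random_library(
    parts: SequenceParts | None = None,
    group_size: int = 5,
    groups: tuple[tuple[int, ...], tuple[int, ...]] | None = None,
    orientations: tuple[str, ...] = ("boxb_5prime", "boxb_3prime"),
    seed: int = 0,
) -> list[OligoRecord]:
    """Recorder-context library: non-A recorder positions randomized.

    Non-A positions are randomized in two groups of ``group_size``
    positions, each enumerated over all four bases, yielding
    ``2 * 4**group_size`` target sequences (one OligoRecord per target
    per orientation).  The designed adenosines are never altered, so
    the editing sites are invariant across the pool.
    """
    parts = parts or SequenceParts()
    if groups is None:
        groups = default_recorder_groups(parts, group_size)
    targets: list[tuple[int, str]] = []
    for gi, positions in enumerate(groups):
        for combo in itertools.product(DNA_BASES, repeat=len(positions)):
            rec = list(parts.recorder)
            for p, b in zip(positions, combo):
                rec[p] = b
            targets.append((gi, "".join(rec)))
    n_oligos = len(targets) * len(orientations)
    barcodes = generate_barcodes(n_oligos, seed=seed)
    bc_iter = iter(barcodes)
    records = []
    for gi, rec in targets:
        for orientation in orientations:
            if orientation == "boxb_3prime":
                segments = [
                    ("spacer", parts.spacer),
                    ("recorder", rec),
                    ("buffer", parts.barcode_buffer),
                    ("boxb", parts.boxb_stemloop),
                ]
            else:
                segments = [
                    ("boxb", parts.boxb_stemloop),
                    ("buffer", parts.barcode_buffer),
                    ("recorder", rec),
                    ("spacer", parts.spacer),
                ]
            oid = f"recorder_g{gi}_{rec}_{orientation}"
            records.append(
                _assemble(
                    parts,
                    next(bc_iter),
                    segments,
                    {"recorder"},
                    orientation,
                    "recorder_random",
                    oid,
                    meta={"group": gi, "stemloop": parts.boxb_stemloop},
                )
            )
    return records


#: 1-based loop positions of the 19-nt boxB stem loop
LOOP_POSITIONS = (8, 9, 10, 11, 12)


def design_stemloop_library(
    parts: SequenceParts | None = None,
    window: tuple[int, int] = (3, 6),
    orientations: tuple[str, ...] = ("boxb_5prime", "boxb_3prime"),
    seed: int = 0,
) -> list[OligoRecord]:
    """Stem-loop library: a window of the boxB stem loop fully randomized.

    ``window`` is a 1-based inclusive position range within the 19-nt
    stem loop (loop = positions 8-12).  All ``4**width`` variants are
    enumerated; records are labeled ``loop_random`` when the window lies
    within the loop and ``stem_random`` otherwise.
    """
    parts = parts or SequenceParts()
    lo, hi = window
    if not (1 <= lo <= hi <= 19):
        raise ValueError("window must lie within stem-loop positions 1..19")
    width = hi - lo + 1
    in_loop = lo >= LOOP_POSITIONS[0] and hi <= LOOP_POSITIONS[-1]
    design_class = "loop_random" if in_loop else "stem_random"
    variants = []
    for combo in itertools.product(DNA_BASES, repeat=width):
        sl = list(parts.boxb_stemloop)
        sl[lo - 1 : hi] = combo
        variants.append("".join(sl))
    n_oligos = len(variants) * len(orientations)
    barcodes = generate_barcodes(n_oligos, seed=seed)
    bc_iter = iter(barcodes)
    records = []
    for sl in variants:
        for orientation in orientations:
            if orientation == "boxb_3prime":
                segments = [
                    ("spacer", parts.spacer),
                    ("recorder", parts.recorder),
                    ("buffer", parts.barcode_buffer),
                    ("boxb", sl),
                ]
            else:
                segments = [
                    ("boxb", sl),
                    ("buffer", parts.barcode_buffer),
                    ("recorder", parts.recorder),
                    ("spacer", parts.spacer),
                ]
            oid = f"{design_class}_{sl}_{orientation}"
            records.append(
                _assemble(
                    parts,
                    next(bc_iter),
                    segments,
                    {"boxb"},
                    orientation,
                    design_class,
                    oid,
                    meta={"window": window, "stemloop": sl},
                )
            )
    return records


def design_dms_library(
    orf: str,
    parts: SequenceParts | None = None,
    barcode_len: int = 20,
    barcodes_per_variant: int = 1,
    seed: int = 0,
) -> tuple[list[OligoRecord], pd.DataFrame]:
    """Deep-mutational-scanning library over a peptide ORF.

    Every codon of ``orf`` is replaced by each of the 64 NNN codons,
    yielding ``n_codons * 64`` variant ORFs.  Each variant is linked to
    ``barcodes_per_variant`` A-depleted barcodes of ``barcode_len`` nt;
    reads are keyed by barcode downstream, so the reporter itself is
    identical across variants.  Returns the records and the
    ground-truth barcode→variant map.
    """
    parts = parts or SequenceParts()
    orf = orf.upper()
    if len(orf) % 3 != 0:
        raise ValueError("ORF length must be divisible by 3")
    if any(b not in DNA_BASES for b in orf):
        raise ValueError("ORF contains non-ACGT characters")
    n_codons = len(orf) // 3
    codons = ["".join(c) for c in itertools.product(DNA_BASES, repeat=3)]
    variants = []
    for pos in range(n_codons):
        for codon in codons:
            var_orf = orf[: 3 * pos] + codon + orf[3 * (pos + 1) :]
            aa = str(Seq(codon).translate())
            variants.append((pos + 1, codon, aa, var_orf))
    n_barcodes = len(variants) * barcodes_per_variant
    barcodes = generate_barcodes(n_barcodes, length=barcode_len, seed=seed)
    bc_iter = iter(barcodes)
    records = []
    map_rows = []
    for pos, codon, aa, var_orf in variants:
        for rep in range(barcodes_per_variant):
            bc = next(bc_iter)
            segments = [
                ("buffer", parts.barcode_buffer),
                ("recorder", parts.recorder),
                ("buffer2", parts.barcode_buffer),
                ("boxb", parts.boxb_stemloop),
            ]
            oid = f"dms_p{pos}_{codon}_b{rep}"
            records.append(
                _assemble(
                    parts,
                    bc,
                    segments,
                    {"barcode"},
                    "boxb_3prime",
                    "dms",
                    oid,
                    meta={
                        "codon_position": pos,
                        "codon": codon,
                        "amino_acid": aa,
                        "orf": var_orf,
                        "stemloop": parts.boxb_stemloop,
                    },
                )
            )
            map_rows.append(
                {
                    "barcode": bc,
                    "orf_sequence": var_orf,
                    "codon_position": pos,
                    "codon": codon,
                    "amino_acid": aa,
                }
            )
    return records, pd.DataFrame(map_rows)


# ---------------------------------------------------------------------------
# annotation table + FASTA I/O
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "barcode",
    "insert_start",
    "insert_length",
    "recorder_start",
    "recorder_length",
    "upstream_flank",
    "downstream_flank",
    "orientation",
    "design_class",
]


def annotations_frame(records: list[OligoRecord]) -> pd.DataFrame:
    """Annotation table (one row per barcode) consumed by the read processor."""
    barcodes = [r.barcode for r in records]
    if len(set(barcodes)) != len(barcodes):
        dupes = {b for b in barcodes if barcodes.count(b) > 1}
        raise ValueError(f"duplicate barcodes in design: {sorted(dupes)[:5]}")
    rows = [
        {
            "barcode": r.barcode,
            "insert_start": r.variable_start,
            "insert_length": r.variable_length,
            "recorder_start": r.recorder_start,
            "recorder_length": r.recorder_length,
            "upstream_flank": r.upstream_flank,
            "downstream_flank": r.downstream_flank,
            "orientation": r.orientation,
            "design_class": r.design_class,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotations(records: list[OligoRecord], path) -> pd.DataFrame:
    frame = annotations_frame(records)
    frame.to_csv(path, index=False)
    return frame


def read_annotations(path) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        dtype={
            "barcode": str,
            "upstream_flank": str,
            "downstream_flank": str,
            "orientation": str,
            "design_class": str,
        },
        keep_default_na=False,
    )
    for col in ("insert_start", "insert_length", "recorder_start", "recorder_length"):
        frame[col] = frame[col].astype(int)
    return frame[ANNOTATION_COLUMNS]


def write_fasta(records: list[OligoRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.oligo_id}\n{r.full_sequence}\n")
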