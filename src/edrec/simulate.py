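"""Synthetic sequencing data with recruitment-dependent editing.

The generator stands in for the study's raw reads: it emulates paired
short reads (79-nt Read 1 over barcode/recorder/variable region, 7-nt
UMI Read 2) and full-length long reads, with ground-truth tables, so
every downstream stage is testable without external downloads.

Editing follows a two-layer model.  The probability that a designed
adenosine is edited in a given read is::

    p_site = background + time_scale * context_rate * occupancy

where ``context_rate`` depends on the designed 5'/3' flanking bases of
that adenosine (purines merged to ``R``), and ``occupancy`` is a
logistic function of a linear binding score over the boxB variant's
features (GNRNA loop, U at position 7, Watson-Crick closing pair,
stem stability).  The model's role is ordinal fidelity — variants that
bind better are edited more — not thermodynamic realism.  Default
context rates follow the enzyme's measured context bias: 5'-U contexts
highest (UAU above all), 5'-C contexts lowest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binding import BoxBVariant, classify_variant
from .design import (
    BOXB_MOTIF,
    OligoRecord,
    READ1_LENGTH,
    SequenceParts,
    UMI_LENGTH,
)
from .energy import hairpin_free_energy
from .readproc import DEFAULT_A_OFFSETS, EditTally

BASES = "ACGT"

#: default per-site editing rates at full occupancy, keyed by the
#: (5' flank, 3' flank) classes with A/G merged to R
DEFAULT_CONTEXT_RATES = {
    ("U", "U"): 0.35,
    ("U", "C"): 0.116,
    ("U", "R"): 0.175,
    ("C", "U"): 0.02,
    ("C", "C"): 0.012,
    ("C", "R"): 0.015,
    ("R", "U"): 0.05,
    ("R", "C"): 0.03,
    ("R", "R"): 0.04,
}


def merge_purine(base: str) -> str:
    """Collapse a designed flanking base to its context class (RNA)."""
    base = base.upper().replace("T", "U")
    return "R" if base in ("A", "G") else base


@dataclass(frozen=True)
class EditingModel:
    """Parameters coupling boxB binding strength to recorder editing."""

    context_rates: dict = field(default_factory=lambda: dict(DEFAULT_CONTEXT_RATES))
    intercept: float = -4.0
    gnrna_bonus: float = 1.5
    u7_bonus: float = 1.0
    closing_pair_bonus: float = 0.5
    dg_weight: float = 0.15
    background_rate: float = 0.005
    time_scale: float = 1.0
    concentration_scale: float = 1.0
    seq_error_rate: float = 0.0

    def __post_init__(self):
        for key, rate in self.context_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"context rate {key} outside [0, 1]")
        for name in ("background_rate", "seq_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")


def binding_score(variant: BoxBVariant, model: EditingModel) -> float:
    """Linear feature score of a boxB variant under ``model``.

    score = intercept + gnrna_bonus·[GNRNA] + u7_bonus·[U7]
            + closing_pair_bonus·[WC pair 7:13] + dg_weight·(−ΔG)
    """
    if variant.delta_g is None:
        raise ValueError(f"variant {variant.stemloop_seq} has no delta_g")
    has_wc = variant.closing_class in ("UA_wildtype", "other_WC")
    return (
        model.intercept
        + model.gnrna_bonus * float(variant.is_gnrna)
        + model.u7_bonus * float(variant.stemloop_seq[6] == "U")
        + model.closing_pair_bonus * float(has_wc)
        + model.dg_weight * (-variant.delta_g)
    )


def occupancy(variant: BoxBVariant, model: EditingModel) -> float:
    """Fractional occupancy: logistic of the binding score.

    The binding score plays the role of a log association constant, so
    occupancy follows the binding isotherm c·K/(1 + c·K): the enzyme
    concentration multiplier shifts the score by log(c).  A saturating
    concentration drives every variant's occupancy toward 1, erasing
    rank differences between binders and non-binders.
    """
    z = binding_score(variant, model) + math.log(model.concentration_scale)
    return 1.0 / (1.0 + math.exp(-z))


def site_probabilities(
    recorder_seq: str,
    a_offsets: tuple[int, ...],
    model: EditingModel,
    occ: float,
) -> np.ndarray:
    """Per-site edit probability for each designed adenosine."""
    probs = []
    for off in a_offsets:
        if off == 0 or off == len(recorder_seq) - 1:
            rate = 0.0  # no flanking context within the recorder
        else:
            key = (merge_purine(recorder_seq[off - 1]), merge_purine(recorder_seq[off + 1]))
            rate = model.context_rates.get(key, 0.0)
        probs.append(model.background_rate + model.time_scale * rate * occ)
    return np.clip(np.asarray(probs), 0.0, 1.0)


def _record_occupancy(
    record: OligoRecord,
    model: EditingModel,
    occupancy_override: dict | None,
    cache: dict,
) -> float:
    if occupancy_override and record.oligo_id in occupancy_override:
        return float(occupancy_override[record.oligo_id])
    stemloop = record.meta.get("stemloop")
    if stemloop is None:
        raise ValueError(f"record {record.oligo_id} carries no stemloop")
    if stemloop not in cache:
        variant = classify_variant(stemloop)
        variant.delta_g = hairpin_free_energy(stemloop)
        cache[stemloop] = occupancy(variant, model)
    return cache[stemloop]


@dataclass
class ReadTruth:
    """Ground truth for one simulated read."""

    read_id: str
    oligo_id: str
    umi: str
    edited_offsets: tuple[int, ...]  # recorder-relative
    error_offsets: tuple[int, ...]  # Read-1-relative


def simulate_reads(
    records: list[OligoRecord],
    model: EditingModel,
    n_reads_per_variant: int,
    seed: int,
    r1_path,
    r2_path,
    truth_path=None,
    a_offsets: tuple[int, ...] = DEFAULT_A_OFFSETS,
    occupancy_override: dict | None = None,
) -> list[ReadTruth]:
    """Write paired FASTQ files plus a truth table for a designed pool.

    Each designed adenosine is edited independently with its site
    probability; UMIs are drawn uniformly (collisions allowed, so
    deduplication is exercised); per-base substitution errors are
    applied to Read 1 after editing.
    """
    if n_reads_per_variant < 1:
        raise ValueError("n_reads_per_variant must be >= 1")
    rng = np.random.default_rng(seed)
    occ_cache: dict = {}
    truths: list[ReadTruth] = []
    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    read_counter = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for record in records:
            template = record.read1_template
            if len(template) < READ1_LENGTH:
                raise ValueError(
                    f"{record.oligo_id}: Read-1 window shorter than required regions"
                )
            occ = _record_occupancy(record, model, occupancy_override, occ_cache)
            probs = site_probabilities(record.recorder_seq, a_offsets, model, occ)
            edited = rng.random((n_reads_per_variant, len(a_offsets))) < probs
            n_errors = rng.binomial(
                READ1_LENGTH, model.seq_error_rate, size=n_reads_per_variant
            )
            umi_idx = rng.integers(0, 4, size=(n_reads_per_variant, UMI_LENGTH))
            for i in range(n_reads_per_variant):
                read_id = f"read{read_counter:07d}"
                read_counter += 1
                seq = bytearray(template.encode())
                ed_offs = tuple(
                    a_offsets[j] for j in np.flatnonzero(edited[i])
                )
                for off in ed_offs:
                    seq[record.recorder_start + off] = ord("G")
                err_offs = []
                if n_errors[i]:
                    positions = rng.choice(
                        READ1_LENGTH, size=n_errors[i], replace=False
                    )
                    for pos in positions:
                        current = seq[pos]
                        choices = base_arr[base_arr != current]
                        seq[pos] = rng.choice(choices)
                        err_offs.append(int(pos))
                umi = "".join(BASES[k] for k in umi_idx[i])
                f1.write(f"@{read_id}\n{seq.decode()}\n+\n{'I' * len(seq)}\n")
                f2.write(f"@{read_id}\n{umi}\n+\n{'I' * UMI_LENGTH}\n")
                truths.append(
                    ReadTruth(read_id, record.oligo_id, umi, ed_offs, tuple(sorted(err_offs)))
                )
    if truth_path is not None:
        write_truth_table(truths, truth_path)
    return truths


def write_truth_table(truths: list[ReadTruth], path) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "read_id": [t.read_id for t in truths],
            "oligo_id": [t.oligo_id for t in truths],
            "umi": [t.umi for t in truths],
            "edited_offsets": [";".join(map(str, t.edited_offsets)) for t in truths],
            "error_offsets": [";".join(map(str, t.error_offsets)) for t in truths],
        }
    )
    frame.to_csv(path, index=False)
    return frame


def simulate_tallies(
    records: list[OligoRecord],
    model: EditingModel,
    n_reads_per_variant: int,
    seed: int,
    a_offsets: tuple[int, ...] = DEFAULT_A_OFFSETS,
    occupancy_override: dict | None = None,
) -> dict[str, EditTally]:
    """Sample editing tallies directly, without materializing reads.

    Equivalent to running error-free output of :func:`simulate_reads`
    through the read processor with all-distinct UMIs; used for large
    parameter-recovery simulations.  Tallies for records sharing a
    variant key (e.g. the two orientations) are merged.
    """
    rng = np.random.default_rng(seed)
    occ_cache: dict = {}
    tallies: dict[str, EditTally] = {}
    n_sites = len(a_offsets)
    for record in records:
        occ = _record_occupancy(record, model, occupancy_override, occ_cache)
        probs = site_probabilities(record.recorder_seq, a_offsets, model, occ)
        edited = rng.random((n_reads_per_variant, n_sites)) < probs
        key = record.variant_key
        tally = tallies.get(key)
        if tally is None:
            tally = EditTally(
                variant_key=key,
                refa_offsets=tuple(a_offsets),
                design_class=record.design_class,
            )
            tallies[key] = tally
        g_per_site = edited.sum(axis=0)
        tally.base_counts[:, 2] += g_per_site  # G
        tally.base_counts[:, 0] += n_reads_per_variant - g_per_site  # A
        tally.edit_histogram += np.bincount(
            edited.sum(axis=1), minlength=n_sites + 1
        )
        tally.umi_count += n_reads_per_variant
    return tallies


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------


def make_longread_references(
    seed: int = 0, length: int = 240, insertion_pos: int = 120
) -> tuple[str, str, int]:
    """Synthetic full-length reporter references with/without boxB.

    The two references are identical except for the boxB motif inserted
    at ``insertion_pos``; the 40 nt immediately 3' of the insertion
    site form the scored editing window.
    """
    rng = np.random.default_rng(seed)
    body = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
    ref_without = body
    ref_with = body[:insertion_pos] + BOXB_MOTIF + body[insertion_pos:]
    return ref_with, ref_without, insertion_pos


def simulate_longreads(
    boxb_present: bool,
    per_a_edit_prob: float,
    indel_rate: float,
    n: int,
    seed: int,
    references: tuple[str, str, int] | None = None,
    path=None,
) -> list[tuple[str, str]]:
    """Simulate full-length reporter reads for the low-throughput assay.

    A→G edits are applied to adenosines within the 40-nt window 3' of
    the insertion site; with probability ``indel_rate`` a read receives
    a random single-base insertion or deletion (such reads are
    discarded downstream).
    """
    if not 0.0 <= per_a_edit_prob <= 1.0 or not 0.0 <= indel_rate <= 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    from .readproc import LONGREAD_WINDOW

    if references is None:
        references = make_longread_references()
    ref_with, ref_without, ins = references
    if boxb_present:
        ref, wstart = ref_with, ins + (len(ref_with) - len(ref_without))
    else:
        ref, wstart = ref_without, ins
    rng = np.random.default_rng(seed)
    a_positions = [
        i for i in range(wstart, min(wstart + LONGREAD_WINDOW, len(ref)))
        if ref[i] == "A"
    ]
    reads = []
    for i in range(n):
        seq = list(ref)
        for pos in a_positions:
            if rng.random() < per_a_edit_prob:
                seq[pos] = "G"
        if rng.random() < indel_rate:
            pos = int(rng.integers(0, len(seq)))
            if rng.random() < 0.5:
                seq.insert(pos, BASES[rng.integers(0, 4)])
            else:
                del seq[pos]
        reads.append((f"longread{i:06d}", "".join(seq)))
    if path is not None:
        with open(path, "w") as fh:
            for name, seq in reads:
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return reads


# ---------------------------------------------------------------------------
# DMS linking reads
# ---------------------------------------------------------------------------


def simulate_linking_reads(
    barcode_variant_map: pd.DataFrame,
    reads_per_barcode: int,
    seed: int,
    error_rate: float = 0.0,
) -> list[tuple[str, str]]:
    """Simulate (barcode, variant ORF) linking-read pairs for DMS.

    Substitution errors at ``error_rate`` per base are applied to the
    ORF sequence only, emulating imperfect linking sequencing.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for row in barcode_variant_map.itertuples():
        for _ in range(reads_per_barcode):
            orf = row.orf_sequence
            if error_rate > 0:
                seq = bytearray(orf.encode())
                n_err = rng.binomial(len(seq), error_rate)
                if n_err:
                    for pos in rng.choice(len(seq), size=n_err, replace=False):
                        current = seq[pos]
                        others = [b for b in BASES.encode() if b != current]
                        seq[pos] = others[rng.integers(0, 3)]
                orf = seq.decode()
            pairs.append((row.barcode, orf))
    return pairs
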