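"""Deep mutational scanning of the λN RNA-binding peptide.

Each λN codon variant is expressed as a TadA fusion in cells carrying
a boxB reporter; editing of the reporter's recorder region reads out
how well the variant peptide still recruits the enzyme.  Variants are
identified by 20-nt A-depleted barcodes placed in the reporter 3' UTR
and linked to their codon by separate linking sequencing.

Scoring follows the normalization used for such screens: the
bootstrapped mean fraction of reads with ≥1 edit is computed per
(codon position, amino acid) by pooling reads across linked barcodes,
then expressed as a log2 ratio against the wild-type mean.  The
bootstrap resamples barcodes (the unit of biological replication)
rather than reads.  Variants supported by fewer than three barcodes
are flagged as low-support.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .readproc import EditTally

#: the 22-residue λN RNA-binding peptide
LAMBDA_N_PEPTIDE = "MDAQTRRRERRAEKQAQWKAAN"

#: a synthetic wild-type nucleotide ORF for the λN peptide (the screen
#: needs *a* coding sequence; any codon choice translating to the
#: peptide works, this one uses common human codons)
LAMBDA_N_ORF_SYNTHETIC = (
    "ATGGACGCCCAGACCCGGCGGCGGGAGCGGCGGGCCGAGAAGCAGGCCCAGTGGAAGGCCGCCAAC"
)

STOP = "*"


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class VariantCall:
    """A decoded single-codon variant (or wild-type identity)."""

    is_wildtype: bool
    codon_position: int | None  # 1-based; None for exact wild-type
    codon: str | None
    amino_acid: str | None  # one-letter, '*' for stop

    @property
    def label(self) -> str:
        if self.is_wildtype:
            return "wild_type"
        return f"{self.codon_position}:{self.amino_acid}"


class AmbiguousVariantError(ValueError):
    """Variant region differs from the reference at more than one codon."""


def call_variant(variant_region_seq: str, reference_orf: str) -> VariantCall:
    """Identify the single differing codon of a variant ORF.

    Returns a wild-type call when the sequences are identical, raises
    :class:`AmbiguousVariantError` when more than one codon differs.
    """
    seq = variant_region_seq.upper()
    ref = reference_orf.upper()
    if len(seq) != len(ref):
        raise ValueError("variant region length differs from reference ORF")
    if len(ref) % 3 != 0:
        raise ValueError("reference ORF length not divisible by 3")
    diffs = [
        i for i in range(len(ref) // 3)
        if seq[3 * i : 3 * i + 3] != ref[3 * i : 3 * i + 3]
    ]
    if not diffs:
        return VariantCall(True, None, None, None)
    if len(diffs) > 1:
        raise AmbiguousVariantError(
            f"{len(diffs)} codons differ from the reference"
        )
    pos = diffs[0]
    codon = seq[3 * pos : 3 * pos + 3]
    return VariantCall(False, pos + 1, codon, translate_codon(codon))


def link_barcodes(
    linking_reads,
    reference_orf: str,
    min_support: int = 2,
    min_purity: float = 0.8,
) -> tuple[pd.DataFrame, dict]:
    """Resolve each barcode to its majority variant.

    ``linking_reads`` yields (barcode, variant_region_seq) pairs.
    A barcode is kept when its majority call has at least
    ``min_support`` reads and makes up at least ``min_purity`` of its
    decodable reads.  Reads differing from the reference at more than
    one codon are discarded and counted.
    """
    votes: dict[str, Counter] = defaultdict(Counter)
    counters = {"reads_in": 0, "undecodable": 0, "barcodes_dropped": 0}
    for barcode, seq in linking_reads:
        counters["reads_in"] += 1
        try:
            call = call_variant(seq, reference_orf)
        except (AmbiguousVariantError, ValueError):
            counters["undecodable"] += 1
            continue
        key = (
            ("wild_type", None, None)
            if call.is_wildtype
            else (call.codon_position, call.codon, call.amino_acid)
        )
        votes[barcode][key] += 1
    rows = []
    for barcode, counter in votes.items():
        (key, support) = counter.most_common(1)[0]
        total = sum(counter.values())
        purity = support / total
        if support < min_support or purity < min_purity:
            counters["barcodes_dropped"] += 1
            continue
        if key[0] == "wild_type":
            pos, codon, aa = None, None, None
            is_wt = True
        else:
            pos, codon, aa = key
            is_wt = False
        rows.append(
            {
                "barcode": barcode,
                "is_wildtype": is_wt,
                "codon_position": pos,
                "codon": codon,
                "amino_acid": aa,
                "support_reads": support,
                "purity": purity,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "barcode", "is_wildtype", "codon_position", "codon",
            "amino_acid", "support_reads", "purity",
        ],
    )
    return frame, counters


@dataclass
class DmsScore:
    codon_position: int
    amino_acid: str
    n_barcodes: int
    mean_frac_ge1: float
    ci_low: float
    ci_high: float
    log2_ratio_vs_wt: float | None
    flagged_low_support: bool


def _barcode_arrays(
    barcodes: list[str], tallies: dict[str, EditTally]
) -> tuple[np.ndarray, np.ndarray]:
    ge1 = np.array(
        [int(tallies[b].edit_histogram[1:].sum()) for b in barcodes], dtype=float
    )
    umis = np.array([tallies[b].umi_count for b in barcodes], dtype=float)
    return ge1, umis


def _bootstrap_mean_frac(
    ge1: np.ndarray, umis: np.ndarray, iters: int, rng
) -> tuple[float, float, float]:
    """Pooled fraction of reads with >=1 edit, with cluster-bootstrap CI.

    The point estimate is the plug-in pooled fraction (the center the
    barcode bootstrap converges to, reported exactly so identical
    groups score identically); the CI resamples barcodes.
    """
    n = len(ge1)
    total = umis.sum()
    point = float(ge1.sum() / total) if total else math.nan
    if n == 1:
        return point, point, point
    idx = rng.integers(0, n, size=(iters, n))
    num = ge1[idx].sum(axis=1)
    den = umis[idx].sum(axis=1)
    fracs = np.divide(num, den, out=np.full(iters, np.nan), where=den > 0)
    low, high = np.nanpercentile(fracs, [2.5, 97.5])
    return point, float(low), float(high)


def score_variants(
    tallies: dict[str, EditTally],
    barcode_variant_map: pd.DataFrame,
    wt_peptide: str = LAMBDA_N_PEPTIDE,
    wt_definition: str = "synonymous",
    reference_orf: str | None = None,
    iters: int = 1000,
    seed: int = 0,
    min_barcodes: int = 3,
) -> tuple[list[DmsScore], dict]:
    """Score every (codon position, amino acid) variant against wild type.

    ``wt_definition='synonymous'`` pools every barcode whose variant
    translates to the full wild-type peptide (identity plus synonymous
    single-codon replacements); ``'codon'`` uses only barcodes carrying
    the exact wild-type nucleotide sequence (requires ``reference_orf``
    or an ``is_wildtype`` column in the map to identify them).
    Synonymous variants are additionally scored as their own
    (position, amino acid) groups so the wild-type cells of the variant
    matrix are populated.
    """
    if wt_definition not in ("synonymous", "codon"):
        raise ValueError("wt_definition must be 'synonymous' or 'codon'")
    rng = np.random.default_rng(seed)
    mapped = barcode_variant_map.set_index("barcode")
    groups: dict[tuple[int, str], list[str]] = defaultdict(list)
    wt_barcodes: list[str] = []
    counters = {"barcodes_tallied": 0, "barcodes_unmapped": 0}
    for barcode in tallies:
        if barcode not in mapped.index:
            counters["barcodes_unmapped"] += 1
            continue
        counters["barcodes_tallied"] += 1
        row = mapped.loc[barcode]
        if bool(row.get("is_wildtype", False)) or pd.isna(row["codon_position"]):
            wt_barcodes.append(barcode)
            continue
        pos = int(row["codon_position"])
        codon = str(row["codon"])
        aa = str(row["amino_acid"])
        exact_wt = (
            reference_orf is not None
            and codon == reference_orf.upper()[3 * (pos - 1) : 3 * pos]
        )
        synonymous = aa == wt_peptide[pos - 1]
        if exact_wt or (synonymous and wt_definition == "synonymous"):
            wt_barcodes.append(barcode)
        if not exact_wt:
            groups[(pos, aa)].append(barcode)

    if not wt_barcodes:
        raise ValueError("no wild-type barcodes found; cannot normalize")
    wt_ge1, wt_umis = _barcode_arrays(wt_barcodes, tallies)
    wt_mean, _, _ = _bootstrap_mean_frac(wt_ge1, wt_umis, iters, rng)
    if not wt_mean or math.isnan(wt_mean):
        raise ValueError("wild-type mean editing is zero; normalization impossible")
    counters["wt_barcodes"] = len(wt_barcodes)
    counters["wt_mean_frac_ge1"] = wt_mean

    scores = []
    for (pos, aa), barcodes in sorted(groups.items()):
        ge1, umis = _barcode_arrays(barcodes, tallies)
        mean, low, high = _bootstrap_mean_frac(ge1, umis, iters, rng)
        log2_ratio = (
            math.log2(mean / wt_mean) if mean and not math.isnan(mean) else None
        )
        scores.append(
            DmsScore(
                codon_position=pos,
                amino_acid=aa,
                n_barcodes=len(barcodes),
                mean_frac_ge1=mean,
                ci_low=low,
                ci_high=high,
                log2_ratio_vs_wt=log2_ratio,
                flagged_low_support=len(barcodes) < min_barcodes,
            )
        )
    return scores, counters


def scores_frame(scores: list[DmsScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "codon_position": s.codon_position,
                "amino_acid": s.amino_acid,
                "n_barcodes": s.n_barcodes,
                "mean_frac_ge1": s.mean_frac_ge1,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "log2_ratio_vs_wt": s.log2_ratio_vs_wt,
                "flagged_low_support": s.flagged_low_support,
            }
            for s in scores
        ]
    )


def score_matrix(scores: list[DmsScore], n_positions: int) -> pd.DataFrame:
    """Position × amino-acid matrix of log2 ratios for heatmap rendering."""
    order = list("ACDEFGHIKLMNPQRSTVWY") + [STOP]
    mat = pd.DataFrame(
        np.nan, index=order, columns=range(1, n_positions + 1)
    )
    for s in scores:
        if s.log2_ratio_vs_wt is not None:
            mat.loc[s.amino_acid, s.codon_position] = s.log2_ratio_vs_wt
    return mat


def residue_summary(
    scores: list[DmsScore],
    wt_peptide: str = LAMBDA_N_PEPTIDE,
    include_stops: bool = False,
) -> pd.DataFrame:
    """Per-position mean log2 ratio over nonsynonymous substitutions.

    Synonymous variants (amino acid equal to the wild-type residue) are
    excluded; stops are excluded unless ``include_stops``.  Positions
    with no eligible scores are omitted.
    """
    by_pos: dict[int, list[float]] = defaultdict(list)
    counts: dict[int, int] = defaultdict(int)
    for s in scores:
        if s.log2_ratio_vs_wt is None:
            continue
        if s.amino_acid == wt_peptide[s.codon_position - 1]:
            continue
        if s.amino_acid == STOP and not include_stops:
            continue
        by_pos[s.codon_position].append(s.log2_ratio_vs_wt)
        counts[s.codon_position] += 1
    rows = [
        {
            "codon_position": pos,
            "wt_residue": wt_peptide[pos - 1],
            "mean_log2_ratio": float(np.mean(vals)),
            "n_variants": counts[pos],
        }
        for pos, vals in sorted(by_pos.items())
    ]
    return pd.DataFrame(
        rows, columns=["codon_position", "wt_residue", "mean_log2_ratio", "n_variants"]
    )
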