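"""Variant-level analysis of boxB stem-loop libraries.

λN binds the boxB hairpin through a GNRNA pentaloop (positions 8-12 of
the 19-nt stem loop; consensus G at 8, purine at 10, A at 12) closed by
the U7·A13 base pair.  This module classifies stem-loop variants by
those features, attaches a predicted folding free energy, and provides
the group comparisons used to relate editing efficiency to binding:
UMI-count/closing-pair filtering, free-energy percentile binning,
rank-sum tests between variant groups, position-wise base summaries,
and cross-condition rank correlation.

All positions are 1-based on the 19-nt stem loop, matching the
conventional boxB residue numbering; loop = positions 8-12.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .energy import hairpin_free_energy

WILDTYPE_STEMLOOP = "GGGCCCTGAAGAAGGGCCC"

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


@dataclass
class BoxBVariant:
    """A boxB stem-loop variant with its binding-relevant features."""

    stemloop_seq: str  # RNA alphabet, length 19
    loop_seq: str
    closing_pair: tuple[str, str]  # bases at positions 7 and 13
    is_gnrna: bool
    closing_class: str  # UA_wildtype | other_WC | mismatch
    delta_g: float | None = None
    mean_site_frequency: float | None = None
    frac_reads_ge1: float | None = None
    umi_count: int = 0
    meta: dict = field(default_factory=dict)


def classify_variant(stemloop_seq: str) -> BoxBVariant:
    """Populate GNRNA and closing-pair flags for a 19-nt stem loop.

    GNRNA: G at position 8, purine at position 10, A at position 12
    (positions 9 and 11 free).  Closing classes: the wild-type U7·A13
    pair, any other Watson-Crick pair, or a mismatch (wobble pairs are
    counted as mismatches here since they were not distinguished from
    unpaired variants in the binding analyses).
    """
    seq = stemloop_seq.strip().upper().replace("T", "U")
    if len(seq) != 19:
        raise ValueError(f"stem loop must be 19 nt, got {len(seq)}")
    if any(b not in "ACGU" for b in seq):
        raise ValueError(f"invalid bases in stem loop: {stemloop_seq!r}")
    loop = seq[7:12]  # positions 8-12
    p7, p13 = seq[6], seq[12]
    is_gnrna = loop[0] == "G" and loop[2] in "AG" and loop[4] == "A"
    if (p7, p13) == ("U", "A"):
        closing = "UA_wildtype"
    elif (p7, p13) in _WC_PAIRS:
        closing = "other_WC"
    else:
        closing = "mismatch"
    return BoxBVariant(
        stemloop_seq=seq,
        loop_seq=loop,
        closing_pair=(p7, p13),
        is_gnrna=is_gnrna,
        closing_class=closing,
    )


def annotate_free_energy(variants: list[BoxBVariant], engine: str = "internal") -> None:
    for v in variants:
        v.delta_g = hairpin_free_energy(v.stemloop_seq, engine=engine)


@dataclass(frozen=True)
class EnergyBins:
    """Percentile bins of the ΔG distribution, most stable first."""

    edges: tuple[float, ...]  # (min ΔG of bin, ...) informational
    assignments: tuple[tuple[int, ...], ...]  # indices into the input list

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(a) for a in self.assignments)


def assign_energy_bins(variants: list[BoxBVariant], n_bins: int = 5) -> EnergyBins:
    """Split variants into ``n_bins`` near-equal ΔG bins.

    Variants are sorted ascending by ΔG (most stable first), ties broken
    lexicographically by sequence, then sliced into bins whose sizes
    differ by at most one (earlier bins take the extra variant).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(variants) < n_bins:
        raise ValueError(f"{len(variants)} variants cannot fill {n_bins} bins")
    for v in variants:
        if v.delta_g is None:
            raise ValueError(f"variant {v.stemloop_seq} has no delta_g")
    order = sorted(
        range(len(variants)),
        key=lambda i: (variants[i].delta_g, variants[i].stemloop_seq),
    )
    chunks = np.array_split(np.asarray(order), n_bins)
    edges = tuple(float(variants[c[0]].delta_g) for c in chunks)
    return EnergyBins(
        edges=edges, assignments=tuple(tuple(int(i) for i in c) for c in chunks)
    )


def filter_variants(
    variants: list[BoxBVariant],
    min_umis: int = 200,
    require_closing_ua: bool = False,
) -> list[BoxBVariant]:
    """Keep variants with strictly more than ``min_umis`` UMIs.

    With ``require_closing_ua`` only variants whose closing pair is
    exactly U7·A13 survive (the filter used before loop-motif
    comparisons, so loop effects are not confounded by a broken stem).
    """
    kept = [v for v in variants if v.umi_count > min_umis]
    if require_closing_ua:
        kept = [v for v in kept if v.closing_class == "UA_wildtype"]
    return kept


def compare_groups(group_a, group_b) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of two efficiency groups."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_a": int(a.size),
        "n_b": int(b.size),
        "p_two_sided": float(res.pvalue),
    }


def positionwise_summary(
    variants: list[BoxBVariant],
    positions: list[int],
    metric: str = "frac_reads_ge1",
) -> pd.DataFrame:
    """Mean editing as a function of the bases at given stem-loop positions.

    Groups variants by the tuple of bases at ``positions`` (1-based) and
    reports the mean of ``metric`` and the group size.
    """
    for p in positions:
        if not 1 <= p <= 19:
            raise ValueError(f"position {p} outside 1..19")
    rows = []
    for v in variants:
        val = getattr(v, metric)
        if val is None:
            continue
        rows.append(
            {"bases": tuple(v.stemloop_seq[p - 1] for p in positions), "value": val}
        )
    frame = pd.DataFrame(rows)
    if frame.empty:
        return pd.DataFrame(columns=["bases", "mean", "n"])
    out = (
        frame.groupby("bases")["value"]
        .agg(mean="mean", n="size")
        .reset_index()
        .sort_values("bases", ignore_index=True)
    )
    out["n"] = out["n"].astype(int)
    return out


def correlate_conditions(summary_x: dict, summary_y: dict) -> tuple[float, int]:
    """Spearman correlation of per-variant efficiencies between conditions.

    ``summary_x`` and ``summary_y`` map variant keys to efficiencies;
    the correlation is computed over the key intersection.
    """
    shared = sorted(set(summary_x) & set(summary_y))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared variant keys, got {len(shared)}")
    x = [summary_x[k] for k in shared]
    y = [summary_y[k] for k in shared]
    rho = stats.spearmanr(x, y).statistic
    return float(rho), len(shared)
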