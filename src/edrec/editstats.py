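"""Editing-efficiency metrics, bootstrap intervals, and context profiles.

Two summary metrics are used throughout:

* ``mean_site_frequency`` — the mean over designed adenosine sites of
  the per-site G frequency among deduplicated reads;
* ``frac_reads_ge_k`` — the fraction of reads carrying at least ``k``
  edits (default 1), the "reads with 1 or more edit" metric.

Confidence intervals are parametric binomial bootstraps: the observed
proportion p̂ is resampled as ``iters`` binomial draws of the original
size, and the 2.5/97.5 percentiles of the resampled proportions are
reported.  Context profiles average per-site frequencies by the
designed 5'/3' flanking bases of each adenosine, optionally collapsing
flanking A and G into a single purine class R — an edited A is
indistinguishable from a G, so the two cannot be resolved in
randomized flanks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import OligoRecord
from .readproc import EditTally
from .simulate import EditingModel, merge_purine


@dataclass(frozen=True)
class EditingSummary:
    mean_site_frequency: float
    frac_reads_ge_k: float
    ci_low: float | None
    ci_high: float | None
    n_umis: int
    k: int = 1

    @property
    def is_empty(self) -> bool:
        return self.n_umis == 0


def summarize_editing(
    tally: EditTally,
    k: int = 1,
    ci: bool = False,
    iters: int = 100_000,
    seed: int = 0,
) -> EditingSummary:
    """Point metrics (and optional bootstrap CI on the ≥k fraction)."""
    if tally.umi_count == 0:
        return EditingSummary(math.nan, math.nan, None, None, 0, k)
    n = tally.umi_count
    g_counts = tally.base_counts[:, 2]
    mean_site = float(g_counts.mean()) / n
    ge_k = int(tally.edit_histogram[k:].sum())
    frac = ge_k / n
    low = high = None
    if ci:
        low, high = bootstrap_ci(ge_k, n, iters=iters, seed=seed)
    return EditingSummary(mean_site, frac, low, high, n, k)


def bootstrap_ci(
    successes: int,
    trials: int,
    iters: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """95% binomial-bootstrap interval for a proportion.

    Resamples ``iters`` binomial counts of size ``trials`` at
    p̂ = successes/trials and returns the 2.5/97.5 percentile bounds of
    the resampled proportions (the coin-flip resampling scheme used for
    binary per-read outcomes).  Deterministic given ``seed``.
    """
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    if iters < 1:
        raise ValueError("iters must be >= 1")
    p_hat = successes / trials
    rng = np.random.default_rng(seed)
    draws = rng.binomial(trials, p_hat, size=iters) / trials
    low, high = np.percentile(draws, [2.5, 97.5])
    return float(low), float(high)


# ---------------------------------------------------------------------------
# sequence-context profiles
# ---------------------------------------------------------------------------


def site_context_labels(
    recorder_seq: str,
    a_offsets: tuple[int, ...],
    merge_purines: bool = True,
) -> list[tuple[str, str, str] | None]:
    """Per-site (5' class, 3' class, trinucleotide label), RNA alphabet.

    Sites at the recorder boundary (no flank on one side) yield None.
    """
    rna = recorder_seq.upper().replace("T", "U")
    labels = []
    for off in a_offsets:
        if off == 0 or off >= len(rna) - 1:
            labels.append(None)
            continue
        five, three = rna[off - 1], rna[off + 1]
        if merge_purines:
            five, three = merge_purine(five), merge_purine(three)
        labels.append((five, three, f"{five}A{three}"))
    return labels


def _recorder_map(designs: list[OligoRecord]) -> dict[str, str]:
    """variant_key -> designed recorder sequence."""
    out: dict[str, str] = {}
    for record in designs:
        out.setdefault(record.variant_key, record.recorder_seq)
    return out


def context_profile(
    tallies: dict[str, EditTally],
    designs: list[OligoRecord],
    merge_purines: bool = True,
) -> pd.DataFrame:
    """Read-weighted mean editing frequency per flanking-base context.

    Each (variant, site) pair contributes its G count and UMI count to
    the context row given by the *designed* flanking bases of that
    adenosine.  ``mean_freq`` is total G / total reads, so un-merged
    rows aggregate exactly to merged rows.  Boundary sites without a
    flank are excluded and counted in ``n_excluded_sites``.
    """
    recorders = _recorder_map(designs)
    agg: dict[tuple[str, str, str], dict] = {}
    excluded = 0
    for key, tally in tallies.items():
        recorder = recorders.get(key)
        if recorder is None:
            continue
        labels = site_context_labels(recorder, tally.refa_offsets, merge_purines)
        for i, label in enumerate(labels):
            if label is None:
                excluded += 1
                continue
            row = agg.setdefault(
                label, {"n_sites": 0, "n_reads": 0, "g_total": 0}
            )
            row["n_sites"] += 1
            row["n_reads"] += tally.umi_count
            row["g_total"] += int(tally.base_counts[i, 2])
    rows = [
        {
            "ctx5": k[0],
            "ctx3": k[1],
            "label": k[2],
            "n_sites": v["n_sites"],
            "n_reads": v["n_reads"],
            "mean_freq": v["g_total"] / v["n_reads"] if v["n_reads"] else math.nan,
        }
        for k, v in sorted(agg.items())
    ]
    frame = pd.DataFrame(
        rows, columns=["ctx5", "ctx3", "label", "n_sites", "n_reads", "mean_freq"]
    )
    frame.attrs["n_excluded_sites"] = excluded
    return frame


def recover_model_rates(
    profile: pd.DataFrame,
    model: EditingModel,
    occupancy: float = 1.0,
) -> pd.DataFrame:
    """Compare a merged context profile against its generating model.

    For each context row the generating per-site probability is
    ``background + time_scale * context_rate * occupancy``; the z score
    is (estimate − truth) / binomial SE.  Contexts with zero reads are
    flagged and excluded from z computation.
    """
    rows = []
    for row in profile.itertuples():
        key = (row.ctx5, row.ctx3)
        if key not in model.context_rates:
            raise KeyError(f"context {key} absent from model (need merged profile)")
        truth = min(
            model.background_rate
            + model.time_scale * model.context_rates[key] * occupancy,
            1.0,
        )
        if row.n_reads == 0:
            rows.append(
                {
                    "ctx5": row.ctx5, "ctx3": row.ctx3, "true_rate": truth,
                    "estimated_rate": math.nan, "n_reads": 0, "z": math.nan,
                    "excluded": True,
                }
            )
            continue
        se = math.sqrt(max(truth * (1 - truth), 1e-12) / row.n_reads)
        z = (row.mean_freq - truth) / se
        rows.append(
            {
                "ctx5": row.ctx5, "ctx3": row.ctx3, "true_rate": truth,
                "estimated_rate": row.mean_freq, "n_reads": int(row.n_reads),
                "z": z, "excluded": False,
            }
        )
    return pd.DataFrame(rows)


def replicate_standard_error(values) -> float:
    """Standard error of the mean over technical replicates."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        return math.nan
    return float(arr.std(ddof=1) / math.sqrt(arr.size))
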