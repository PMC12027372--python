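"""Hairpin folding free energy.

Two engines are exposed:

* ``internal`` – a deliberately minimal single-hairpin nearest-neighbor
  model: the structure space is restricted to one contiguous helix
  closed by one terminal loop, which matches the 19-nt boxB stem-loop
  libraries this package analyses.  Stack free energies are the
  standard Watson-Crick nearest-neighbor values at 37 °C (kcal/mol);
  stacks involving a G·U wobble pair use a single representative
  value.  Positive totals are clamped to 0 (treated as unfolded).
* ``external`` – delegates to an installed ``RNAfold`` executable
  (ViennaRNA) and parses its minimum free energy.  This is the full
  secondary-structure model and is used to cross-check the internal
  ranking.

Energies are invariant under T↔U in the input.
"""

from __future__ import annotations

import math
import re
import shutil
import subprocess
from functools import lru_cache

#: Watson-Crick stack free energies, ΔG°37 kcal/mol.  Key is the two
#: consecutive base pairs read 5'→3' on the top strand:
#: 5'-XY-3' / 3'-X'Y'-5' is keyed ((X, X'), (Y, Y')).
_WC_STACKS = {
    (("A", "U"), ("A", "U")): -0.93,
    (("A", "U"), ("U", "A")): -1.10,
    (("U", "A"), ("A", "U")): -1.33,
    (("C", "G"), ("U", "A")): -2.08,
    (("C", "G"), ("A", "U")): -2.11,
    (("G", "C"), ("U", "A")): -2.24,
    (("G", "C"), ("A", "U")): -2.35,
    (("C", "G"), ("G", "C")): -2.36,
    (("G", "C"), ("G", "C")): -3.26,
    (("G", "C"), ("C", "G")): -3.42,
}

#: representative stack value when either pair is a G·U wobble
_WOBBLE_STACK = -1.2

#: hairpin loop initiation penalties by loop size (Jacobson-Stockmayer
#: extrapolation beyond 9)
_HAIRPIN_INIT = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}

_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def _hairpin_init(size: int) -> float:
    if size in _HAIRPIN_INIT:
        return _HAIRPIN_INIT[size]
    return _HAIRPIN_INIT[9] + 1.07 * math.log(size / 9.0)


def _stack(p1: tuple[str, str], p2: tuple[str, str]) -> float:
    if p1 in _WOBBLE or p2 in _WOBBLE:
        return _WOBBLE_STACK
    if (p1, p2) in _WC_STACKS:
        return _WC_STACKS[(p1, p2)]
    # a stack read in the reverse direction has the same free energy
    rev = ((p2[1], p2[0]), (p1[1], p1[0]))
    return _WC_STACKS[rev]


def _as_rna(seq: str) -> str:
    seq = seq.strip().upper().replace("T", "U")
    if not seq or any(b not in "ACGU" for b in seq):
        raise ValueError(f"not a nucleotide sequence: {seq!r}")
    return seq


#: internal-loop penalties by (bases skipped 5' side, bases skipped 3' side)
_LOOP_PENALTY = {(1, 1): 1.5, (1, 2): 2.2, (2, 1): 2.2, (2, 2): 2.0}
#: single-nucleotide bulge penalty (flanking pairs still stack)
_BULGE1 = 3.8
#: two-nucleotide bulge penalty (no flanking stack)
_BULGE2 = 2.8


@lru_cache(maxsize=65536)
def _internal_mfe(seq: str) -> float:
    """Best single-hairpin energy: one terminal loop, one helix that may
    be interrupted by 1-nt bulges and small internal loops."""
    n = len(seq)

    ext_cache: dict[tuple[int, int], float] = {}

    def extend(a: int, b: int) -> float:
        """Best additional energy extending the helix outward of pair (a, b)."""
        key = (a, b)
        if key in ext_cache:
            return ext_cache[key]
        best = 0.0
        inner = (seq[a], seq[b])
        for da in range(3):
            for db in range(3):
                a2, b2 = a - 1 - da, b + 1 + db
                if a2 < 0 or b2 >= n:
                    continue
                outer = (seq[a2], seq[b2])
                if outer not in _CANONICAL:
                    continue
                if da == 0 and db == 0:
                    step = _stack(outer, inner)
                elif (da, db) in ((0, 1), (1, 0)):
                    step = _BULGE1 + _stack(outer, inner)
                elif (da, db) in ((0, 2), (2, 0)):
                    step = _BULGE2
                else:
                    step = _LOOP_PENALTY[(da, db)]
                best = min(best, step + extend(a2, b2))
        ext_cache[key] = best
        return best

    best = 0.0
    # enumerate the terminal loop [i..j] closed by pair (i-1, j+1)
    for i in range(1, n - 3):
        for j in range(i + 2, n - 1):  # loop size >= 3
            closing = (seq[i - 1], seq[j + 1])
            if closing not in _CANONICAL:
                continue
            e = _hairpin_init(j - i + 1) + extend(i - 1, j + 1)
            best = min(best, e)
    return min(best, 0.0)


_MFE_RE = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def _external_mfe(seq: str) -> float:
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError(
            "RNAfold executable not found; use engine='internal' instead"
        )
    proc = subprocess.run(
        [exe, "--noPS"],
        input=seq + "\n",
        capture_output=True,
        text=True,
        check=True,
    )
    for line in proc.stdout.splitlines():
        m = _MFE_RE.search(line)
        if m:
            return float(m.group(1))
    raise RuntimeError(f"could not parse RNAfold output: {proc.stdout!r}")


def hairpin_free_energy(seq: str, engine: str = "internal") -> float:
    """Predicted folding free energy of ``seq`` in kcal/mol (≤ 0).

    ``engine='internal'`` uses the single-hairpin nearest-neighbor
    model; ``engine='external'`` shells out to RNAfold.
    """
    rna = _as_rna(seq)
    if engine == "internal":
        return _internal_mfe(rna)
    if engine == "external":
        return _external_mfe(rna)
    raise ValueError(f"unknown folding engine {engine!r}")
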