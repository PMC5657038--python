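"""Motif significance statistics and the motif decision rule.

For each pattern m, the empirical p-value is the fraction of random
replicates whose frequency reaches the observed one,

    p(m) = (1/N) * sum_n [ f_R(m) >= f_G(m) ],

and the z-score is (f_G(m) - mean(f_R(m))) / std(f_R(m)) with the
population (divide-by-N) standard deviation.  A pattern is called a motif
when p < 0.01 or z > 2.0 (strict inequalities, disjunctive rule).  When
std is zero the z-score is undefined (NaN) and only the p-rule can fire;
patterns absent from the input graph (f_G = 0) are never motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import IO, Sequence

import numpy as np

from .patterns import PatternID

__all__ = [
    "MotifStats", "p_value", "z_score", "compute_stats", "find_motifs",
    "write_count_report", "DEFAULT_P_THRESHOLD", "DEFAULT_Z_THRESHOLD",
]

DEFAULT_P_THRESHOLD = 0.01
DEFAULT_Z_THRESHOLD = 2.0


@dataclass(frozen=True)
class MotifStats:
    """Per-pattern frequency, ensemble statistics and the motif flag."""

    pattern: PatternID
    f_g: int
    mean_fr: float
    std_fr: float
    z: float          # NaN when the ensemble is degenerate (std = 0)
    p: float
    is_motif: bool = False


def p_value(f_g: int, f_r: Sequence[int]) -> float:
    """Fraction of replicates with f_R(m) >= f_G(m); ties count."""
    if len(f_r) == 0:
        raise ValueError("empty ensemble: need at least one replicate")
    return sum(1 for x in f_r if x >= f_g) / len(f_r)


def z_score(f_g: int, f_r: Sequence[int]) -> float:
    """(f_G - mean(f_R)) / std(f_R), population std; NaN when std = 0."""
    if len(f_r) == 0:
        raise ValueError("empty ensemble: need at least one replicate")
    arr = np.asarray(f_r, dtype=float)
    std = float(arr.std())          # ddof=0
    if std == 0.0:
        return math.nan
    return (f_g - float(arr.mean())) / std


def compute_stats(freq_g: dict[PatternID, int],
                  ensemble: dict[PatternID, list[int]]) -> list[MotifStats]:
    """Assemble per-pattern statistics, sorted by canonical pattern value.

    Covers the union of patterns seen in the input graph and the ensemble;
    motif flags start False (apply :func:`find_motifs`).
    """
    rows = []
    all_patterns = set(freq_g) | set(ensemble)
    n_random = max((len(v) for v in ensemble.values()), default=0)
    for pid in sorted(all_patterns):
        f_g = freq_g.get(pid, 0)
        f_r = ensemble.get(pid, [0] * n_random if n_random else [])
        arr = np.asarray(f_r, dtype=float)
        rows.append(MotifStats(
            pattern=pid,
            f_g=f_g,
            mean_fr=float(arr.mean()) if len(f_r) else 0.0,
            std_fr=float(arr.std()) if len(f_r) else 0.0,
            z=z_score(f_g, f_r) if len(f_r) else math.nan,
            p=p_value(f_g, f_r) if len(f_r) else 1.0,
        ))
    return rows


def find_motifs(stats: Sequence[MotifStats],
                p_threshold: float = DEFAULT_P_THRESHOLD,
                z_threshold: float = DEFAULT_Z_THRESHOLD) -> list[MotifStats]:
    """Apply the disjunctive motif rule; returns rows with flags set.

    is_motif = f_G > 0 and (p < p_threshold or (z defined and z > z_threshold)).
    """
    if not (math.isfinite(p_threshold) and math.isfinite(z_threshold)):
        raise ValueError("thresholds must be finite")
    out = []
    for row in stats:
        flag = row.f_g > 0 and (
            row.p < p_threshold or (not math.isnan(row.z) and row.z > z_threshold)
        )
        out.append(replace(row, is_motif=flag))
    return out


def write_count_report(stats: Sequence[MotifStats], dest: IO[str] | str) -> None:
    """Tab-separated per-pattern report: ID, adjacency bits, f_G, ensemble
    mean/std, z, p, motif flag.  Undefined z rendered as ``NA``."""
    close = False
    if isinstance(dest, str):
        dest = open(dest, "w", encoding="utf-8")
        close = True
    try:
        dest.write("pattern_id\tadjacency\tf_G\tmean_fR\tstd_fR\tz_score\tp_value\tis_motif\n")
        for row in stats:
            z_txt = "NA" if math.isnan(row.z) else f"{row.z:.6g}"
            dest.write(
                f"{row.pattern.value}\t{row.pattern.bitstring}\t{row.f_g}\t"
                f"{row.mean_fr:.6g}\t{row.std_fr:.6g}\t{z_txt}\t{row.p:.6g}\t"
                f"{int(row.is_motif)}\n"
            )
    finally:
        if close:
            dest.close()
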