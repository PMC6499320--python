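"""Regulatory and sequence statistics.

* TFBS-SV independence: per TSS-relative position, a 2x2 contingency table
  over genes (TFBS presence x SV presence) is tested for independence, and
  the conditional probability P_x(SV | TFBS) = P_x(TFBS and SV) / P_x(TFBS)
  is reported together with the association sign.
* Linguistic complexity: CL = (sum_i V_i) / (sum_i Vmax_i) over word sizes
  i = 1..N in a sliding window, with Vmax_i = min(K^i, N - i + 1) for
  alphabet size K.
* List enrichment: one-sided Fisher's exact (hypergeometric upper tail) of
  list hits against population hits, with optional Benjamini-Hochberg
  adjustment across categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnnotationTrack, GeneModel

DNA_ALPHABET = "ACGT"


# ---------------------------------------------------------------------------
# TFBS-SV independence around the TSS
# ---------------------------------------------------------------------------

def indicator_tracks(
    gene_models: Sequence[GeneModel],
    tfbs_track: AnnotationTrack,
    sv_intervals: Sequence,
    flank: int = 500,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene boolean indicator tracks over [TSS - flank, TSS + flank].

    Regions are strand-flipped so position -flank is always upstream.
    Returns (positions, tfbs, sv) with indicator shape (n_genes, 2*flank+1).
    """
    n_pos = 2 * flank + 1
    positions = np.arange(-flank, flank + 1)
    tfbs = np.zeros((len(gene_models), n_pos), dtype=bool)
    sv = np.zeros((len(gene_models), n_pos), dtype=bool)

    sv_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for v in sv_intervals:
        start = getattr(v, "rep_start", getattr(v, "start", None))
        end = getattr(v, "rep_end", getattr(v, "end", None))
        sv_by_chrom.setdefault(v.chrom, []).append((start, max(end, start + 1)))

    def mark(row: np.ndarray, gene: GeneModel, start: int, end: int) -> None:
        if gene.strand == "+":
            lo, hi = start - gene.tss, end - gene.tss
        else:
            lo, hi = gene.tss - end + 1, gene.tss - start + 1
        lo, hi = max(lo, -flank), min(hi, flank + 1)
        if hi > lo:
            row[lo + flank : hi + flank] = True

    for gi, gene in enumerate(gene_models):
        for rec in tfbs_track.by_chrom(gene.chrom):
            mark(tfbs[gi], gene, rec.start, rec.end)
        for start, end in sv_by_chrom.get(gene.chrom, []):
            mark(sv[gi], gene, start, end)
    return positions, tfbs, sv


def tfbs_sv_independence(
    tfbs: np.ndarray,
    sv: np.ndarray,
    positions: Optional[np.ndarray] = None,
    method: str = "fisher",
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-position independence test between TFBS and SV presence.

    ``tfbs`` and ``sv`` are boolean (n_genes, n_positions) indicators.  Per
    position, the genes x {TFBS, SV} 2x2 table is tested two-sided.
    Methods: ``"fisher"`` (exact; the default — conservative at small
    margins because of the discreteness of the hypergeometric null),
    ``"midp"`` (Fisher's mid-p: half-weights the observed table, giving
    type-I error close to nominal), ``"chi2"`` (asymptotic, no continuity
    correction).  Positions where no gene carries a TFBS get a missing
    conditional probability and no test.  Raw p-values are the default;
    ``adjust=True`` adds a Benjamini-Hochberg column.
    """
    if tfbs.shape != sv.shape:
        raise ValueError("indicator arrays must have identical shape")
    n_genes, n_pos = tfbs.shape
    if n_genes < 2:
        raise ValueError("at least two genes required")
    if positions is None:
        positions = np.arange(n_pos)

    rows = []
    for x in range(n_pos):
        t, s = tfbs[:, x], sv[:, x]
        n_both = int(np.sum(t & s))
        n_tfbs = int(np.sum(t))
        n_sv = int(np.sum(s))
        n_neither = n_genes - n_tfbs - n_sv + n_both
        p_tfbs = n_tfbs / n_genes
        p_sv = n_sv / n_genes
        p_joint = n_both / n_genes
        conditional = p_joint / p_tfbs if n_tfbs > 0 else np.nan
        sign = int(np.sign(n_both * n_neither - (n_tfbs - n_both) * (n_sv - n_both)))
        if n_tfbs == 0:
            p_value = np.nan
        else:
            table = [[n_both, n_tfbs - n_both], [n_sv - n_both, n_neither]]
            if method == "fisher":
                p_value = float(stats.fisher_exact(table, alternative="two-sided")[1])
            elif method == "midp":
                p_value = _fisher_midp(n_both, n_tfbs, n_sv, n_genes)
            elif method == "chi2":
                try:
                    p_value = float(
                        stats.chi2_contingency(table, correction=False)[1]
                    )
                except ValueError:  # degenerate margin
                    p_value = np.nan
            else:
                raise ValueError("method must be 'fisher', 'midp' or 'chi2'")
        rows.append(
            {
                "position": int(positions[x]),
                "n_genes": n_genes, "n_tfbs": n_tfbs, "n_sv": n_sv,
                "n_both": n_both,
                "p_tfbs": p_tfbs, "p_sv": p_sv, "p_joint": p_joint,
                "p_sv_given_tfbs": conditional,
                "sign": sign, "p_value": p_value,
            }
        )
    table = pd.DataFrame(rows)
    if adjust:
        mask = table["p_value"].notna()
        adjusted = np.full(len(table), np.nan)
        if mask.any():
            adjusted[mask.to_numpy()] = stats.false_discovery_control(
                table.loc[mask, "p_value"].to_numpy()
            )
        table["p_adjusted"] = adjusted
    return table


def _fisher_midp(n_both: int, n_tfbs: int, n_sv: int, n_genes: int) -> float:
    """Two-sided Fisher mid-p: tables strictly less probable than the
    observed one count fully, equally probable ones at half weight."""
    rv = stats.hypergeom(n_genes, n_tfbs, n_sv)
    support = np.arange(max(0, n_tfbs + n_sv - n_genes), min(n_tfbs, n_sv) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(n_both)
    eps = 1e-12
    lower = pmf[pmf < p_obs * (1.0 - eps)].sum()
    ties = pmf[np.abs(pmf - p_obs) <= p_obs * eps].sum()
    return float(min(lower + 0.5 * ties, 1.0))


# ---------------------------------------------------------------------------
# Linguistic complexity
# ---------------------------------------------------------------------------

def _max_vocabulary(n: int, k: int) -> int:
    return sum(min(k ** i, n - i + 1) for i in range(1, n + 1))


def window_complexity(window: str, k: int = 4) -> float:
    """CL of one window: observed distinct substrings of sizes 1..N over the
    maximum possible number for a window of that length."""
    n = len(window)
    if n < 1:
        raise ValueError("window must be non-empty")
    observed = 0
    for i in range(1, n + 1):
        observed += len({window[j : j + i] for j in range(n - i + 1)})
    return observed / _max_vocabulary(n, k)


@dataclass
class ComplexityProfile:
    """Per-window-start CL values (NaN where the window contains characters
    outside the alphabet)."""

    values: np.ndarray
    window: int
    alphabet_size: int


def linguistic_complexity(
    sequence: str, window: int = 10, alphabet: str = DNA_ALPHABET
) -> ComplexityProfile:
    """Sliding-window linguistic complexity profile of one sequence.

    Characters outside the alphabet are masked; windows containing masked
    characters are skipped (NaN).
    """
    if window < 1:
        raise ValueError("window size must be >= 1")
    seq = sequence.upper()
    if len(seq) < window:
        raise ValueError("sequence shorter than the window")
    k = len(alphabet)
    valid = np.frombuffer(seq.encode(), dtype=np.uint8)
    ok = np.isin(valid, np.frombuffer(alphabet.encode(), dtype=np.uint8))
    n_windows = len(seq) - window + 1
    values = np.full(n_windows, np.nan)
    # prefix sums of invalid characters for O(1) window-mask checks
    bad = np.concatenate([[0], np.cumsum(~ok)])
    for i in range(n_windows):
        if bad[i + window] - bad[i] == 0:
            values[i] = window_complexity(seq[i : i + window], k)
    return ComplexityProfile(values=values, window=window, alphabet_size=k)


def mean_complexity_profile(
    sequences: Iterable[str], window: int = 10, alphabet: str = DNA_ALPHABET
) -> np.ndarray:
    """Position-wise mean CL across equal-length sequences (NaN-aware), e.g.
    averaging across all promoters."""
    profiles = [
        linguistic_complexity(s, window, alphabet).values for s in sequences
    ]
    if not profiles:
        raise ValueError("no sequences given")
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length for averaging")
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.vstack(profiles), axis=0)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    p_value: float
    odds_ratio: float  # NaN when undefined (zero margin)
    list_hits: int
    list_total: int
    pop_hits: int
    pop_total: int


def enrichment_test(
    list_hits: int, list_total: int, pop_hits: int, pop_total: int
) -> EnrichmentResult:
    """One-sided overrepresentation test (hypergeometric upper tail).

    The p-value is the probability of observing at least ``list_hits`` hits
    when drawing ``list_total`` genes from a population of ``pop_total``
    containing ``pop_hits`` hits.  The sample odds ratio comes from the
    2x2 table; zero margins give p = 1 and an undefined (NaN) odds ratio.
    """
    if not (0 <= list_hits <= list_total <= pop_total):
        raise ValueError("require 0 <= list_hits <= list_total <= pop_total")
    if list_hits > pop_hits or pop_hits > pop_total:
        raise ValueError("require list_hits <= pop_hits <= pop_total")
    a = list_hits
    b = list_total - list_hits
    c = pop_hits - list_hits
    d = (pop_total - pop_hits) - b
    if list_total == 0 or pop_hits == 0 or pop_hits == pop_total:
        return EnrichmentResult(1.0, float("nan"), list_hits, list_total,
                                pop_hits, pop_total)
    p = float(stats.hypergeom.sf(list_hits - 1, pop_total, pop_hits, list_total))
    odds = (a * d) / (b * c) if b * c > 0 else float("nan")
    return EnrichmentResult(min(p, 1.0), odds, list_hits, list_total,
                            pop_hits, pop_total)


def enrichment_table(
    categories: pd.DataFrame, adjust: bool = True
) -> pd.DataFrame:
    """Run :func:`enrichment_test` per category row.

    ``categories`` needs columns list_hits, list_total, pop_hits, pop_total;
    BH-adjusted p-values are added across categories by default.
    """
    results = [
        enrichment_test(
            int(row.list_hits), int(row.list_total),
            int(row.pop_hits), int(row.pop_total),
        )
        for row in categories.itertuples(index=False)
    ]
    out = categories.copy()
    out["p_value"] = [r.p_value for r in results]
    out["odds_ratio"] = [r.odds_ratio for r in results]
    if adjust:
        out["p_adjusted"] = stats.false_discovery_control(out["p_value"].to_numpy())
    return out
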