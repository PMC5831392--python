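"""Count normalization and exact count-based differential expression.

Expression of a miRNA in a library is normalized to transcripts per
million of clean reads:

    TPM = count / total_clean_reads * 1e6

Differential expression between two libraries uses the Audic-Claverie
conditional Poisson test: given ``x`` reads in library 1 (total N1) and
``y`` in library 2 (total N2), the probability of observing y conditional
on x under equal per-read abundance is

    p(y|x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1)

i.e. y | x follows a negative binomial with x+1 successes and success
probability N1/(N1+N2).  The exponent of the last factor is negative;
only then does p(y|x) sum to one over y (the test suite asserts this
normalization).  Tail probabilities include the observed count in both
tails (C = P(Y <= y | x), D = P(Y >= y | x)); the default two-sided
p-value doubles the smaller tail and caps at 1, with a one-sided mode
available.  All probabilities are computed through log-gamma, never raw
factorials.

Significance calls use Bonferroni correction within each pairwise
comparison and require fold change >= 2 (|log2 fc| >= 1) and corrected
p < 0.01 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp


@dataclass
class CountMatrix:
    """miRNA x library raw counts plus per-library clean-read totals.

    ``library_totals`` are the totals of *clean reads* per library (the
    N1/N2 of the conditional test and the TPM denominator), which are at
    least the column sums because not every clean read is a miRNA.
    """

    counts: pd.DataFrame  # index: mirna ids; columns: library names
    library_totals: dict[str, int] = field(default_factory=dict)
    #: Column sums cannot exceed clean-read totals under count-conserving
    #: assignment; "count to each" multi-assignment deliberately breaks
    #: this, so the producer may opt out of the check.
    strict_totals: bool = True

    def __post_init__(self) -> None:
        for lib in self.counts.columns:
            if lib not in self.library_totals:
                raise ValueError(f"missing clean-read total for library {lib!r}")
            if (self.counts[lib] < 0).any():
                raise ValueError("negative counts")
            if self.strict_totals and self.counts[lib].sum() > self.library_totals[lib]:
                raise ValueError(
                    f"column sum exceeds clean-read total for library {lib!r}"
                )

    def to_tsv(self, path: str | Path) -> None:
        frame = self.counts.copy()
        frame.index.name = "mirna"
        with open(path, "w") as fh:
            totals = "\t".join(str(self.library_totals[c]) for c in frame.columns)
            fh.write(f"# library_totals\t{totals}\n")
            frame.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[0] != "# library_totals":
                raise ValueError("count matrix TSV missing library_totals header")
            totals = [int(x) for x in header[1:]]
            frame = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(frame, dict(zip(frame.columns, totals)))


def tpm_normalize(cm: CountMatrix) -> pd.DataFrame:
    """Normalize counts to transcripts per million clean reads."""
    tpm = {}
    for lib in cm.counts.columns:
        total = cm.library_totals[lib]
        if total <= 0:
            raise ValueError(f"non-positive clean-read total for library {lib!r}")
        tpm[lib] = cm.counts[lib] / total * 1e6
    return pd.DataFrame(tpm, index=cm.counts.index)


def log2_fold_change(tpm_a: float, tpm_b: float, pseudocount: float = 0.01) -> float:
    """log2((tpm_a + pseudocount) / (tpm_b + pseudocount))."""
    if tpm_a < 0 or tpm_b < 0:
        raise ValueError("TPM values must be non-negative")
    return math.log2((tpm_a + pseudocount) / (tpm_b + pseudocount))


def _log_ac_pmf(y: np.ndarray, x: int, log_r: float, log_1pr: float) -> np.ndarray:
    """log p(y|x) for an array of y, with r = N2/N1."""
    return (
        y * log_r
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * log_1pr
    )


def ac_probability(y: int, x: int, n1: float, n2: float) -> float:
    """Conditional probability p(y|x) of the Audic-Claverie model."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    r = n2 / n1
    return float(
        np.exp(_log_ac_pmf(np.array([y], dtype=float), x, math.log(r), math.log1p(r)))[0]
    )


def ac_test(
    x: int, y: int, n1: float, n2: float, alternative: str = "two-sided"
) -> float:
    """Audic-Claverie p-value for counts x (library 1) vs y (library 2).

    ``alternative`` is ``"two-sided"`` (doubled smaller tail, capped at 1)
    or ``"one-sided"`` (the smaller tail itself).
    """
    if alternative not in ("two-sided", "one-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    r = n2 / n1
    log_r = math.log(r)
    log_1pr = math.log1p(r)

    # Lower tail C = P(Y <= y | x), exact finite sum in log space.
    ys = np.arange(0, y + 1, dtype=float)
    log_c = logsumexp(_log_ac_pmf(ys, x, log_r, log_1pr))
    lower = float(np.exp(log_c))

    # Upper tail D = P(Y >= y | x).  Sum upward from y until the added
    # mass is negligible; term count is bounded by the geometric decay of
    # the negative binomial tail.
    log_py = float(_log_ac_pmf(np.array([y], dtype=float), x, log_r, log_1pr)[0])
    upper_direct = 1.0 - lower + math.exp(log_py)
    if upper_direct > 1e-8:
        upper = min(1.0, upper_direct)
    else:
        block = 256
        terms = []
        start = y
        while True:
            ys_blk = np.arange(start, start + block, dtype=float)
            log_terms = _log_ac_pmf(ys_blk, x, log_r, log_1pr)
            terms.append(log_terms)
            start += block
            total = logsumexp(np.concatenate(terms))
            if log_terms[-1] < total - 40.0:
                break
        upper = float(np.exp(logsumexp(np.concatenate(terms))))

    if alternative == "one-sided":
        return min(1.0, min(lower, upper))
    return min(1.0, 2.0 * min(lower, upper))


def bonferroni(p_raw: float, m: int) -> float:
    return min(1.0, p_raw * m)


def call_differential(
    cm: CountMatrix,
    pair: tuple[str, str],
    alpha: float = 0.01,
    min_fold: float = 2.0,
    pseudocount: float = 0.01,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Differential expression between two libraries of a count matrix.

    Rows with zero counts in both libraries (e.g. zeroed by the low-count
    floor) are not tested.  The Bonferroni factor m is the number of
    miRNAs tested in this pair.  A miRNA is significant iff
    |log2 fc| >= log2(min_fold) and corrected p < alpha; direction
    reports which library is higher.
    """
    lib_a, lib_b = pair
    for lib in pair:
        if lib not in cm.counts.columns:
            raise ValueError(f"library {lib!r} not in count matrix")
    n1 = cm.library_totals[lib_a]
    n2 = cm.library_totals[lib_b]
    counts_a = cm.counts[lib_a]
    counts_b = cm.counts[lib_b]
    tested = cm.counts.index[(counts_a > 0) | (counts_b > 0)]
    m = len(tested)
    min_l2fc = math.log2(min_fold)

    rows = []
    for mirna in tested:
        x = int(round(counts_a[mirna]))
        y = int(round(counts_b[mirna]))
        tpm_a = counts_a[mirna] / n1 * 1e6
        tpm_b = counts_b[mirna] / n2 * 1e6
        l2fc = log2_fold_change(tpm_a, tpm_b, pseudocount)
        p_raw = ac_test(x, y, n1, n2, alternative)
        p_bonf = bonferroni(p_raw, m)
        significant = abs(l2fc) >= min_l2fc and p_bonf < alpha
        rows.append(
            {
                "mirna": mirna,
                "tpm_a": tpm_a,
                "tpm_b": tpm_b,
                "log2fc": l2fc,
                "p_raw": p_raw,
                "p_bonferroni": p_bonf,
                "significant": significant,
                "direction": "up_in_a" if l2fc >= 0 else "up_in_b",
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "mirna",
            "tpm_a",
            "tpm_b",
            "log2fc",
            "p_raw",
            "p_bonferroni",
            "significant",
            "direction",
        ],
    )
    return result.sort_values(["p_bonferroni", "p_raw", "mirna"]).reset_index(drop=True)


def de_partition(result: pd.DataFrame) -> dict[str, int]:
    """Up/down/total partition of significant calls in a DE result table."""
    sig = result[result["significant"]]
    up = int((sig["direction"] == "up_in_a").sum())
    down = int((sig["direction"] == "up_in_b").sum())
    return {"up_in_a": up, "up_in_b": down, "total": up + down}


def relative_expression_ddct(
    ct_target: float, ct_ref: float, ct_target_cal: float, ct_ref_cal: float
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) - (Ct_target,calibrator -
    Ct_reference,calibrator); returns 2 ** -ddCt.
    """
    for ct in (ct_target, ct_ref, ct_target_cal, ct_ref_cal):
        if ct <= 0:
            raise ValueError("Ct values must be positive")
    ddct = (ct_target - ct_ref) - (ct_target_cal - ct_ref_cal)
    return 2.0 ** (-ddct)
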