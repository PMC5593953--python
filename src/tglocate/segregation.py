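"""Transmission genetics: chi-square goodness of fit and penetrance.

An F2 colony from a het x het cross is summarized by three counts:
transgene-negative animals (A), transgene-positive animals without
glaucoma (B), and glaucomatous animals (C; all glaucomatous animals are
transgene-positive). Two hypotheses are tested:

* Mendelian transmission of the transgene, ignoring phenotype:
  A : (B + C) = 25% : 75%;
* fully penetrant recessive glaucoma: A : B : C = 25% : 50% : 25%.

Rejection of the second together with acceptance of the first is the
signature of a recessive-acting locus with incomplete penetrance; the
penetrance itself is estimated as the observed glaucoma fraction over
the expected homozygote fraction, (C / N) / (1/4).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class TransmissionTable:
    """Colony genotype/phenotype counts (A, B, C above)."""

    label: str
    n_neg: int
    n_pos_normal: int
    n_pos_glaucoma: int

    def __post_init__(self) -> None:
        if min(self.n_neg, self.n_pos_normal, self.n_pos_glaucoma) < 0:
            raise ValueError("counts must be >= 0")
        if self.total == 0:
            raise ValueError("table must contain at least one animal")

    @property
    def total(self) -> int:
        return self.n_neg + self.n_pos_normal + self.n_pos_glaucoma

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_neg, self.n_pos_normal, self.n_pos_glaucoma)

    @property
    def fraction_positive(self) -> float:
        return (self.n_pos_normal + self.n_pos_glaucoma) / self.total

    @property
    def fraction_glaucoma(self) -> float:
        return self.n_pos_glaucoma / self.total


@dataclass(frozen=True)
class GofHypothesis:
    """Expected category proportions for a goodness-of-fit test."""

    proportions: tuple[float, ...]
    label: str

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.proportions):
            raise ValueError("all proportions must be > 0")
        if abs(sum(self.proportions) - 1.0) > 1e-12:
            raise ValueError("proportions must sum to 1")


MENDELIAN_POSITIVE = GofHypothesis((0.25, 0.75), "A 25% : (B+C) 75%")
HOMOZYGOTE_GLAUCOMA = GofHypothesis((0.25, 0.5, 0.25), "A 25% : B 50% : C 25%")


@dataclass(frozen=True)
class GofResult:
    """Pearson chi-square goodness-of-fit result."""

    chi2: float
    df: int
    p: float
    p_rounded: float
    observed: tuple[int, ...]
    expected: tuple[float, ...]
    hypothesis: str

    def summary(self) -> str:
        obs = ", ".join(str(o) for o in self.observed)
        exp = ", ".join(f"{e:.1f}" for e in self.expected)
        return (
            f"H0 {self.hypothesis}: observed ({obs}) vs expected ({exp}); "
            f"chi2 = {self.chi2:.3f}, df = {self.df}, p = {self.p:.4g} "
            f"(rounded {self.p_rounded:.2f})"
        )


def chisq_gof(observed, hypothesis: GofHypothesis) -> GofResult:
    """Uncorrected Pearson chi-square against stated proportions.

    ``p`` is the upper-tail chi-square probability with ``k - 1`` degrees
    of freedom (the regularized upper incomplete gamma function
    ``Q(df/2, chi2/2)``); no continuity correction is applied.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("need >= 2 categories")
    if obs.size != len(hypothesis.proportions):
        raise ValueError("category count does not match hypothesis")
    if (obs < 0).any():
        raise ValueError("negative count")
    expected = obs.sum() * np.asarray(hypothesis.proportions)
    if (expected == 0).any():
        raise ValueError("hypothesis gives a zero expected count")
    chi2, p = stats.chisquare(obs, f_exp=expected)
    df = obs.size - 1
    return GofResult(
        chi2=float(chi2),
        df=df,
        p=float(p),
        p_rounded=round(float(p), 2),
        observed=tuple(int(o) for o in obs),
        expected=tuple(float(e) for e in expected),
        hypothesis=hypothesis.label,
    )


def test_mendelian_positive(table: TransmissionTable) -> GofResult:
    """A vs (B + C) against 1:3 — Mendelian transmission of the transgene."""
    observed = (table.n_neg, table.n_pos_normal + table.n_pos_glaucoma)
    return chisq_gof(observed, MENDELIAN_POSITIVE)


def test_homozygote_glaucoma(table: TransmissionTable) -> GofResult:
    """A vs B vs C against 1:2:1 — fully penetrant homozygote glaucoma."""
    return chisq_gof(table.counts, HOMOZYGOTE_GLAUCOMA)


def estimate_penetrance(table: TransmissionTable) -> tuple[float, bool]:
    """Plug-in penetrance estimate (C / N) / (1/4), clamped to [0, 1].

    Returns ``(estimate, clamped)`` where ``clamped`` flags a raw value
    above 1 (possible by sampling noise when penetrance is near 1).
    """
    raw = table.fraction_glaucoma / 0.25
    return (min(raw, 1.0), raw > 1.0)


def penetrance_interval(table: TransmissionTable, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for the penetrance (not a quantity from the
    source tables; provided as an extra diagnostic).

    The Wilson interval on the glaucoma fraction C/N is scaled by 4 and
    clamped to [0, 1].
    """
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(table.n_pos_glaucoma, table.total, alpha=alpha, method="wilson")
    return (min(1.0, 4 * lo), min(1.0, 4 * hi))


# ------------------------------------------------------------------ tables


def load_tables(path: str | Path) -> list[TransmissionTable]:
    """Load transmission tables from TSV.

    Columns: ``label``, ``total``, ``n_neg``, ``n_pos_normal``,
    ``n_pos_glaucoma``. Exactly one of the three counts may be blank, in
    which case it is reconstructed as ``total - (other two)`` — published
    colony tables often print only two of the three categories plus the
    total.
    """
    df = pd.read_csv(path, sep="\t", dtype={"label": str})
    tables = []
    for _, row in df.iterrows():
        counts = {}
        missing = []
        for col in ("n_neg", "n_pos_normal", "n_pos_glaucoma"):
            v = row[col]
            if pd.isna(v):
                missing.append(col)
            else:
                counts[col] = int(v)
        if missing:
            if len(missing) > 1:
                raise ValueError(f"{row['label']}: more than one missing count")
            if pd.isna(row.get("total")):
                raise ValueError(f"{row['label']}: missing count needs a total")
            counts[missing[0]] = int(row["total"]) - sum(counts.values())
            if counts[missing[0]] < 0:
                raise ValueError(f"{row['label']}: reconstructed {missing[0]} is negative")
        elif not pd.isna(row.get("total")) and int(row["total"]) != sum(counts.values()):
            raise ValueError(f"{row['label']}: counts do not sum to total")
        tables.append(TransmissionTable(label=str(row["label"]), **counts))
    return tables


def packaged_colony_tables() -> dict[str, TransmissionTable]:
    """The two published F2 colony tables shipped with the package.

    ``b6d2f1``: 433 animals, 118 negative, 234 positive-normal (glaucoma
    count reconstructed as 81); ``c57bl6j``: 260 animals, 145
    positive-normal, 48 glaucomatous (negatives reconstructed as 67).
    """
    with resources.as_file(resources.files("tglocate.data") / "colony_tables.tsv") as p:
        tables = load_tables(p)
    return {t.label: t for t in tables}


def segregation_report(tables: list[TransmissionTable]) -> pd.DataFrame:
    """One row per colony: counts, fractions, both tests, penetrance."""
    rows = []
    for t in tables:
        mend = test_mendelian_positive(t)
        homo = test_homozygote_glaucoma(t)
        pen, clamped = estimate_penetrance(t)
        rows.append(
            {
                "label": t.label,
                "n_neg": t.n_neg,
                "n_pos_normal": t.n_pos_normal,
                "n_pos_glaucoma": t.n_pos_glaucoma,
                "total": t.total,
                "frac_positive": t.fraction_positive,
                "frac_glaucoma": t.fraction_glaucoma,
                "p_mendelian": mend.p,
                "p_mendelian_rounded": mend.p_rounded,
                "p_homozygote_glaucoma": homo.p,
                "p_homozygote_glaucoma_rounded": homo.p_rounded,
                "penetrance": pen,
                "penetrance_clamped": clamped,
            }
        )
    return pd.DataFrame(rows)
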