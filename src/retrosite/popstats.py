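"""Population-level summaries of HERV-K genotype matrices.

Prevalence tables, provirus co-occurrence, per-individual burden with a
two-sample Kolmogorov-Smirnov comparison, and Fisher linear discriminant
analysis of either the three-state calls (absence=0, solo LTR=1,
provirus=2) or the continuous n/T ratios, which capture allelic variation
on top of site occupancy.  A synthetic population generator provides
cohorts with controlled per-group state frequencies and allele divergence.

Prevalence counts the provirus state only: solo LTRs and absences are both
non-carriers of the provirus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.stats import kstwo

STATES = ("absence", "solo_LTR", "provirus")
STATE_CODE = {s: i for i, s in enumerate(STATES)}

#: product of sample sizes below which the exact KS null distribution is
#: enumerated instead of using the asymptotic approximation
KS_EXACT_LIMIT = 10_000


@dataclass
class GenotypeMatrix:
    """Individuals x loci state calls and n/T ratios, with population labels."""

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    states: pd.DataFrame  # individuals x loci, values in STATES
    ratios: pd.DataFrame  # individuals x loci, floats in [0, 1]

    def __post_init__(self) -> None:
        if not self.individuals or not self.loci:
            raise ValueError("individuals and loci must be non-empty")
        if len(self.populations) != len(self.individuals):
            raise ValueError("one population label per individual required")
        for df in (self.states, self.ratios):
            if df.shape != (len(self.individuals), len(self.loci)):
                raise ValueError("matrix shape inconsistent with labels")

    def population_of(self, individual: str) -> str:
        return self.populations[self.individuals.index(individual)]

    def members(self, population: str) -> list[str]:
        return [i for i, p in zip(self.individuals, self.populations) if p == population]

    def to_tsv(self, path: str | Path) -> None:
        long = []
        for i, (ind, pop) in enumerate(zip(self.individuals, self.populations)):
            for locus in self.loci:
                long.append(
                    {
                        "individual": ind,
                        "population": pop,
                        "locus": locus,
                        "state": self.states.iloc[i][locus],
                        "ratio": self.ratios.iloc[i][locus],
                    }
                )
        pd.DataFrame(long).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        long = pd.read_csv(path, sep="\t")
        states = long.pivot(index="individual", columns="locus", values="state")
        ratios = long.pivot(index="individual", columns="locus", values="ratio")
        order = long["individual"].drop_duplicates().tolist()
        loci = long["locus"].drop_duplicates().tolist()
        states = states.loc[order, loci]
        ratios = ratios.loc[order, loci]
        pops = long.drop_duplicates("individual").set_index("individual")["population"]
        return cls(
            individuals=order,
            populations=[str(pops[i]) for i in order],
            loci=loci,
            states=states,
            ratios=ratios,
        )


# ---------------------------------------------------------------------------
# prevalence / co-occurrence / burden
# ---------------------------------------------------------------------------


def prevalence(matrix: GenotypeMatrix, population: str, locus: str) -> float:
    """Percent of the population's individuals carrying the provirus state."""
    members = matrix.members(population)
    if not members:
        raise ValueError(f"population {population!r} is empty")
    col = matrix.states.loc[members, locus]
    return 100.0 * (col == "provirus").sum() / len(members)


def prevalence_table(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Loci x populations table of provirus prevalence (percent, 1 d.p.)."""
    pops = list(dict.fromkeys(matrix.populations))
    data = {
        pop: [round(prevalence(matrix, pop, locus), 1) for locus in matrix.loci]
        for pop in pops
    }
    return pd.DataFrame(data, index=matrix.loci)


def cooccurrence(matrix: GenotypeMatrix, loci_combo: Sequence[str], population: str) -> float:
    """Percent of the population carrying the provirus at EVERY combo locus."""
    unknown = set(loci_combo) - set(matrix.loci)
    if unknown:
        raise ValueError(f"unknown loci: {sorted(unknown)}")
    members = matrix.members(population)
    if not members:
        raise ValueError(f"population {population!r} is empty")
    sub = matrix.states.loc[members, list(loci_combo)]
    carriers = (sub == "provirus").all(axis=1).sum()
    return 100.0 * carriers / len(members)


def burden(
    matrix: GenotypeMatrix, polymorphic_loci: Optional[Sequence[str]] = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-individual provirus counts over the polymorphic loci, plus a
    histogram binned by integer count."""
    loci = list(polymorphic_loci) if polymorphic_loci is not None else matrix.loci
    unknown = set(loci) - set(matrix.loci)
    if unknown:
        raise ValueError(f"unknown loci: {sorted(unknown)}")
    counts = (matrix.states[loci] == "provirus").sum(axis=1)
    counts.index = matrix.individuals
    hist = (
        counts.value_counts().sort_index().rename_axis("nProviruses").reset_index(name="nIndividuals")
    )
    return counts, hist


# ---------------------------------------------------------------------------
# two-sample Kolmogorov-Smirnov test
# ---------------------------------------------------------------------------


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """D = sup |ECDF_a - ECDF_b| and the integer lattice height
    h = D * len(a) * len(b)."""
    m, n = len(a), len(b)
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="mergesort")
    # +n per a-step, -m per b-step keeps everything integer
    steps = np.where(order < m, n, -m)
    walk = np.cumsum(steps)
    h = int(np.max(np.abs(walk)))
    # with ties, only evaluate at the end of each tie group
    sorted_pooled = pooled[order]
    group_end = np.r_[sorted_pooled[1:] != sorted_pooled[:-1], True]
    h = int(np.max(np.abs(walk[group_end])))
    return h / (m * n), h


def _ks_exact_pvalue(h: int, m: int, n: int) -> float:
    """P(D >= h/(m n)) by exact lattice-path enumeration (no-ties null).

    Counts monotone paths from (0,0) to (m,n) that keep |i n - j m| < h and
    divides by C(m+n, m); the complement is the attained p-value.
    """
    if h <= 0:
        return 1.0
    ways = [0] * (n + 1)
    ways[0] = 1
    for j in range(1, n + 1):
        ways[j] = ways[j - 1] if abs(j * m) < h else 0
    for i in range(1, m + 1):
        prev = ways[0]
        ways[0] = ways[0] if abs(i * n) < h else 0
        for j in range(1, n + 1):
            cur = 0
            if abs(i * n - j * m) < h:
                cur = ways[j] + ways[j - 1]
            prev, ways[j] = ways[j], cur
    inside = ways[n]
    return 1.0 - inside / comb(m + n, m)


def ks_two_sample(counts_a: Sequence[float], counts_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample, two-sided Kolmogorov-Smirnov test.

    Returns ``(D, p)``.  The p-value is exact (lattice enumeration) when
    ``len(a) * len(b) <= 10^4`` and otherwise uses the asymptotic
    distribution with the effective sample size ``m n / (m + n)``.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    m, n = len(a), len(b)
    d, h = _ks_statistic(a, b)
    if m * n <= KS_EXACT_LIMIT:
        p = _ks_exact_pvalue(h, m, n)
    else:
        en = m * n / (m + n)
        p = float(kstwo.sf(d, int(round(en))))
    return d, min(1.0, max(0.0, p))


# ---------------------------------------------------------------------------
# linear discriminant analysis
# ---------------------------------------------------------------------------


@dataclass
class LdaResult:
    scalings: np.ndarray  # features x components
    eigenvalues: np.ndarray
    projections: np.ndarray  # individuals x components
    group_means: pd.DataFrame  # groups x components
    classes: list[str]
    labels: list[str]

    def separation(self) -> float:
        """Between-group over within-group variance of the first component."""
        x = self.projections[:, 0]
        labels = np.asarray(self.labels)
        overall = x.mean()
        between = within = 0.0
        for cls in self.classes:
            grp = x[labels == cls]
            between += len(grp) * (grp.mean() - overall) ** 2
            within += ((grp - grp.mean()) ** 2).sum()
        return between / within if within > 0 else np.inf


def encode_states(states: pd.DataFrame, one_hot: bool = False) -> np.ndarray:
    """Ordinal 0/1/2 encoding of the three states (one-hot behind a flag)."""
    codes = states.apply(lambda col: col.map(STATE_CODE)).to_numpy(dtype=float)
    if not one_hot:
        return codes
    n, d = codes.shape
    out = np.zeros((n, 3 * d))
    for s in range(3):
        out[:, s::3] = codes == s
    return out


def lda_fit(
    data: GenotypeMatrix | np.ndarray | pd.DataFrame,
    labels: Optional[Sequence[str]] = None,
    encoding: str = "state",
    one_hot: bool = False,
    ridge: float = 1e-6,
) -> LdaResult:
    """Fisher LDA: eigenvectors of ``Sw^-1 Sb`` (pooled within-class inverse
    times between-class scatter).

    ``data`` may be a :class:`GenotypeMatrix` (with ``encoding`` "state" or
    "ratio") or a raw array with explicit ``labels``.  The within-class
    scatter is ridge-regularised by ``ridge * trace(Sw)/d`` so singular
    problems remain solvable; components are ordered by eigenvalue
    descending with the sign convention that the first non-zero loading of
    each component is positive.  Each group needs at least two members.
    """
    if isinstance(data, GenotypeMatrix):
        labels = data.populations
        X = (
            encode_states(data.states, one_hot)
            if encoding == "state"
            else data.ratios.to_numpy(dtype=float)
        )
    else:
        X = np.asarray(data, dtype=float)
        if labels is None:
            raise ValueError("labels required with raw arrays")
    labels = [str(l) for l in labels]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least two groups")
    y = np.asarray(labels)
    n, d = X.shape
    overall = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for cls in classes:
        grp = X[y == cls]
        if len(grp) < 2:
            raise ValueError(f"group {cls!r} has fewer than 2 members")
        mu = grp.mean(axis=0)
        centered = grp - mu
        Sw += centered.T @ centered
        diff = (mu - overall).reshape(-1, 1)
        Sb += len(grp) * (diff @ diff.T)
    eps = ridge * (np.trace(Sw) / d if np.trace(Sw) > 0 else 1.0)
    Sw_reg = Sw + eps * np.eye(d)
    eigvals, eigvecs = eigh(Sb, Sw_reg)
    order = np.argsort(eigvals)[::-1]
    n_comp = min(len(classes) - 1, d)
    eigvals = eigvals[order][:n_comp]
    scalings = eigvecs[:, order][:, :n_comp]
    for c in range(scalings.shape[1]):
        col = scalings[:, c]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            scalings[:, c] = -col
    projections = X @ scalings
    means = pd.DataFrame(
        [projections[y == cls].mean(axis=0) for cls in classes],
        index=classes,
        columns=[f"LD{i + 1}" for i in range(n_comp)],
    )
    return LdaResult(
        scalings=scalings,
        eigenvalues=eigvals,
        projections=projections,
        group_means=means,
        classes=classes,
        labels=labels,
    )


def nearest_centroid_loo_accuracy(result: LdaResult) -> float:
    """Leave-one-out nearest-centroid accuracy in the projected space."""
    X = result.projections
    y = np.asarray(result.labels)
    correct = 0
    for i in range(len(y)):
        keep = np.ones(len(y), dtype=bool)
        keep[i] = False
        best, best_d = None, np.inf
        for cls in result.classes:
            sel = keep & (y == cls)
            if not sel.any():
                continue
            mu = X[sel].mean(axis=0)
            dist = float(((X[i] - mu) ** 2).sum())
            if dist < best_d:
                best, best_d = cls, dist
        correct += best == y[i]
    return correct / len(y)


# ---------------------------------------------------------------------------
# synthetic populations
# ---------------------------------------------------------------------------


def generate_population(
    n_per_group: dict[str, int],
    loci: Sequence[str],
    group_state_freqs: dict[str, Sequence[float] | dict[str, Sequence[float]]],
    allele_noise: float | dict[str, float] = 0.0,
    seed: int = 0,
    solo_ltr_ratio: float = 0.1,
) -> GenotypeMatrix:
    """Synthetic cohort with i.i.d. states per group.

    ``group_state_freqs[group]`` is either one (absence, solo LTR, provirus)
    frequency triple used for all loci or a per-locus mapping of triples.
    Ratios are 1 for a reference-allele provirus and ``1 - allele_noise*U``
    for divergent alleles (``allele_noise`` may vary by group, creating the
    allelic structure that separates populations in ratio space); solo LTRs
    sit near ``solo_ltr_ratio`` and absences at 0.  Reproducible by seed.
    """
    rng = np.random.default_rng(seed)
    individuals: list[str] = []
    populations: list[str] = []
    state_rows = []
    ratio_rows = []
    for group in n_per_group:
        freqs = group_state_freqs[group]
        noise = allele_noise[group] if isinstance(allele_noise, dict) else allele_noise
        for i in range(n_per_group[group]):
            name = f"{group}_{i:03d}"
            individuals.append(name)
            populations.append(group)
            srow = {}
            rrow = {}
            for locus in loci:
                f = np.asarray(freqs[locus] if isinstance(freqs, dict) else freqs, dtype=float)
                if f.shape != (3,) or not np.isclose(f.sum(), 1.0):
                    raise ValueError(f"state frequencies for {group}/{locus} must sum to 1")
                state = STATES[rng.choice(3, p=f)]
                srow[locus] = state
                if state == "provirus":
                    rrow[locus] = 1.0 - noise * rng.random()
                elif state == "solo_LTR":
                    rrow[locus] = solo_ltr_ratio * (1.0 - noise * rng.random())
                else:
                    rrow[locus] = 0.0
            state_rows.append(srow)
            ratio_rows.append(rrow)
    states = pd.DataFrame(state_rows, index=individuals)[list(loci)]
    ratios = pd.DataFrame(ratio_rows, index=individuals)[list(loci)]
    return GenotypeMatrix(
        individuals=individuals,
        populations=populations,
        loci=list(loci),
        states=states,
        ratios=ratios,
    )


# ---------------------------------------------------------------------------
# presentation-only plots
# ---------------------------------------------------------------------------


def plot_lda(result: LdaResult, path: str | Path) -> None:  # pragma: no cover
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    y = np.asarray(result.labels)
    for cls in result.classes:
        pts = result.projections[y == cls]
        if pts.shape[1] > 1:
            ax.scatter(pts[:, 0], pts[:, 1], label=cls, s=14, alpha=0.7)
        else:
            ax.scatter(pts[:, 0], np.zeros(len(pts)), label=cls, s=14, alpha=0.7)
    ax.set_xlabel("LD1")
    ax.set_ylabel("LD2" if result.projections.shape[1] > 1 else "")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_burden_histogram(counts_by_group: dict[str, Sequence[int]], path: str | Path) -> None:  # pragma: no cover
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    all_counts = np.concatenate([np.asarray(v) for v in counts_by_group.values()])
    bins = np.arange(all_counts.min() - 0.5, all_counts.max() + 1.5)
    for label, counts in counts_by_group.items():
        ax.hist(counts, bins=bins, alpha=0.5, label=label, density=True)
    ax.set_xlabel("polymorphic proviruses per genome")
    ax.set_ylabel("fraction of individuals")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
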