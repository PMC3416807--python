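"""Literature co-occurrence maps and forward/reverse Bayesian inference.

Two complementary questions about a term (e.g. "pain") and a pattern of
brain activation:

* association in the literature — how often two terms tag the same
  studies, scored by the natural log of the Jaccard index
  J = |A∩B| / |A∪B| over study sets;
* specificity of activation — the forward inference
  P(activation | term) versus the reverse inference
  P(term | activation), the latter via Bayes' rule with either the
  empirical term base rate or a user-supplied prior (0.5 mimics the
  uniform-prior convention of automated meta-analytic frameworks).

The corpus is a binary study x term and study x region incidence
table; regions may be voxels or named ROIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StudyCorpus",
    "jaccard_association",
    "phenotype_map",
    "forward_inference",
    "reverse_inference",
    "dice_coefficient",
    "specificity_overlap",
]

#: Sentinel for probabilities that are undefined (0/0 counts).
UNDEFINED = float("nan")


@dataclass
class StudyCorpus:
    """Binary incidence of terms and activations across studies.

    ``terms`` and ``activation`` are 0/1 DataFrames sharing the study
    index; ``years`` is optional per-study metadata for trend queries.
    """

    terms: pd.DataFrame
    activation: pd.DataFrame
    years: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.terms.index.equals(self.activation.index):
            raise ValueError("terms and activation must share the study index")
        for df, what in ((self.terms, "terms"), (self.activation, "activation")):
            vals = df.to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"{what} incidence must be binary 0/1")

    @classmethod
    def from_arrays(cls, study_ids, term_names, term_mat, region_names, act_mat, years=None):
        idx = pd.Index(study_ids, name="study_id")
        return cls(
            terms=pd.DataFrame(term_mat, index=idx, columns=list(term_names)),
            activation=pd.DataFrame(act_mat, index=idx, columns=list(region_names)),
            years=None if years is None else pd.Series(years, index=idx, name="year"),
        )

    @property
    def n_studies(self) -> int:
        return len(self.terms)

    def study_set(self, term: str) -> set:
        if term not in self.terms.columns:
            raise KeyError(f"term {term!r} not in corpus")
        col = self.terms[term]
        return set(col.index[col == 1])

    # -- TSV round-trip ------------------------------------------------

    def to_tsv(self, path) -> None:
        df = self.terms.add_prefix("term:").join(self.activation.add_prefix("region:"))
        if self.years is not None:
            df.insert(0, "year", self.years)
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "StudyCorpus":
        df = pd.read_csv(path, sep="\t", index_col=0)
        years = df.pop("year") if "year" in df.columns else None
        terms = df[[c for c in df.columns if c.startswith("term:")]]
        acts = df[[c for c in df.columns if c.startswith("region:")]]
        return cls(
            terms=terms.rename(columns=lambda c: c[len("term:"):]),
            activation=acts.rename(columns=lambda c: c[len("region:"):]),
            years=years,
        )


def jaccard_association(corpus: StudyCorpus, term_a: str, term_b: str) -> tuple[float, float]:
    """Jaccard index over the two terms' study sets, and its natural log.

    Disjoint sets give J = 0 and lnJ = -inf (sentinel, not an error).
    """
    a, b = corpus.study_set(term_a), corpus.study_set(term_b)
    union = a | b
    if not union:
        return 0.0, -math.inf
    j = len(a & b) / len(union)
    return j, (math.log(j) if j > 0 else -math.inf)


def phenotype_map(corpus: StudyCorpus, terms: list[str] | None = None, threshold_lnj: float = -10.0):
    """Pairwise lnJ association matrix plus a thresholded edge list.

    Edges keep term pairs with lnJ strictly above ``threshold_lnj``
    (default -10, revealing only the strongest associations).  Per-term
    association shares are normalized to percentages over that term's
    surviving edges.

    Returns ``(lnj_matrix, edges)`` — a labeled symmetric DataFrame and
    an edge DataFrame with columns term_a, term_b, jaccard, lnj,
    pct_of_a, pct_of_b.
    """
    if terms is None:
        terms = list(corpus.terms.columns)
    n = len(terms)
    lnj = pd.DataFrame(0.0, index=terms, columns=terms)
    jmat = pd.DataFrame(1.0, index=terms, columns=terms)
    rows = []
    for i in range(n):
        for k in range(i + 1, n):
            j, lj = jaccard_association(corpus, terms[i], terms[k])
            jmat.iloc[i, k] = jmat.iloc[k, i] = j
            lnj.iloc[i, k] = lnj.iloc[k, i] = lj
            if lj > threshold_lnj:
                rows.append({"term_a": terms[i], "term_b": terms[k], "jaccard": j, "lnj": lj})
    edges = pd.DataFrame(rows, columns=["term_a", "term_b", "jaccard", "lnj"])
    # association percentage: each edge's share of its endpoint's total J
    totals = {t: 0.0 for t in terms}
    for r in edges.itertuples():
        totals[r.term_a] += r.jaccard
        totals[r.term_b] += r.jaccard
    edges["pct_of_a"] = [
        100.0 * r.jaccard / totals[r.term_a] if totals[r.term_a] > 0 else 0.0 for r in edges.itertuples()
    ]
    edges["pct_of_b"] = [
        100.0 * r.jaccard / totals[r.term_b] if totals[r.term_b] > 0 else 0.0 for r in edges.itertuples()
    ]
    return lnj, edges


def forward_inference(corpus: StudyCorpus, term: str) -> pd.Series:
    """P(activation | term) per region: count(act & term) / count(term)."""
    if term not in corpus.terms.columns:
        raise KeyError(f"term {term!r} not in corpus")
    has_term = corpus.terms[term] == 1
    n_term = int(has_term.sum())
    if n_term == 0:
        return pd.Series(UNDEFINED, index=corpus.activation.columns, name=f"P(act|{term})")
    probs = corpus.activation[has_term].mean(axis=0)
    probs.name = f"P(act|{term})"
    return probs


def reverse_inference(corpus: StudyCorpus, term: str, prior="empirical") -> pd.Series:
    """P(term | activation) per region via Bayes' rule.

    P(term|act) = P(act|term) P(term) /
                  [P(act|term) P(term) + P(act|~term) (1 - P(term))]

    ``prior`` is either ``"empirical"`` (the term's base rate in the
    corpus — in which case the result equals direct counting
    count(term & act)/count(act)) or a number in (0, 1) such as 0.5.
    Regions where P(activation) = 0 under the prior get NaN, never 0.
    """
    if term not in corpus.terms.columns:
        raise KeyError(f"term {term!r} not in corpus")
    has_term = (corpus.terms[term] == 1).to_numpy()
    n, n_term = corpus.n_studies, int(has_term.sum())
    if prior == "empirical":
        p_term = n_term / n
    else:
        p_term = float(prior)
        if not 0.0 <= p_term <= 1.0:
            raise ValueError("prior must be in [0, 1]")
    act = corpus.activation.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        p_act_term = np.where(n_term > 0, act[has_term].sum(axis=0) / max(n_term, 1), UNDEFINED)
        n_not = n - n_term
        p_act_not = np.where(n_not > 0, act[~has_term].sum(axis=0) / max(n_not, 1), 0.0)
        numer = p_act_term * p_term
        denom = numer + p_act_not * (1.0 - p_term)
        post = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), UNDEFINED)
    return pd.Series(post, index=corpus.activation.columns, name=f"P({term}|act)")


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice = 2|A∩B| / (|A| + |B|) on binary arrays (1.0 if both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def specificity_overlap(reverse_map, conjunction, threshold: float = 0.5) -> dict:
    """Agreement between a thresholded reverse-inference map and a
    conjunction map.

    Both inputs are binary or real arrays (or VolumeMaps); the reverse
    map is cut at ``threshold`` (strictly greater), the conjunction map
    at > 0.  Returns Dice plus the raw voxel counts.
    """
    rev = getattr(reverse_map, "values", reverse_map)
    conj = getattr(conjunction, "values", conjunction)
    rev = np.nan_to_num(np.asarray(rev, dtype=float), nan=0.0)
    a = rev > threshold
    b = np.asarray(conj, dtype=float) > 0
    return {
        "dice": dice_coefficient(a, b),
        "n_reverse": int(a.sum()),
        "n_conjunction": int(b.sum()),
        "n_intersection": int((a & b).sum()),
    }
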