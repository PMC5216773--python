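"""Fuzzy-measure (Sugeno lambda-measure) disease semantic similarity.

The pipeline turns each disease's MeSH DAG into a fuzzy density set and
compares diseases through Sugeno measures of their shared terms:

1. *Information content.*  A term's IC is the negative log of its frequency
   across all disease DAGs in the corpus: ``IC(t) = -log(N_DAG(t)/TN_DAG)``.
   Rare (specific) terms score high; a term present in every DAG scores 0.

2. *Fuzzy density.*  ``FD(t) = IC(t) / max_d IC(d)``, the IC normalized by
   the corpus maximum so densities live in [0, 1].  Because a raw density of
   exactly 1 makes the lambda equation rootless in the required interval
   whenever that term co-occurs with others, all densities are scaled by a
   cap slightly below 1 (default 0.999); the scaling preserves ordering.
   Terms with zero IC carry no information and are pruned.

3. *Sugeno lambda.*  Per disease, lambda > -1 solves
   ``1 + lambda = prod_i (1 + lambda * FD(t_i))``,
   which has a unique non-trivial root: in (-1, 0) when the densities sum
   above 1 and in (0, inf) when they sum below 1 (lambda = 0 exactly at an
   additive measure).

4. *Similarity.*  For diseases a and b with shared term set T, the Sugeno
   measure of T is evaluated under each disease's own lambda and the two
   values are averaged.  A disease against itself recovers 1 because the
   lambda equation normalizes the full-set measure to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .mesh import DiseaseDAG

__all__ = [
    "ICTable",
    "FuzzyDensitySet",
    "DiseaseSimilarityMatrix",
    "compute_ic",
    "compute_fuzzy_density",
    "solve_lambda",
    "sugeno_measure",
    "disease_semantic_similarity",
    "build_disease_similarity_matrix",
    "density_sets_from_dags",
]

DEFAULT_DENSITY_CAP = 0.999
LAMBDA_TOL = 1e-12


@dataclass(frozen=True)
class ICTable:
    """Information content of every term seen in the DAG corpus."""

    ic: dict[str, float]
    n_dag: dict[str, int]
    tn_dag: int


@dataclass
class FuzzyDensitySet:
    """A disease's term densities together with its solved Sugeno lambda."""

    disease_id: str
    densities: dict[str, float]
    lam: float | None = None


@dataclass
class DiseaseSimilarityMatrix:
    disease_ids: list[str]
    values: np.ndarray

    def loc(self, a: str, b: str) -> float:
        i = self.disease_ids.index(a)
        j = self.disease_ids.index(b)
        return float(self.values[i, j])


def compute_ic(dags, base: float = math.e) -> ICTable:
    """Count term occurrences across disease DAGs and convert to IC.

    ``base`` selects the logarithm base; the similarity downstream is
    invariant to it because densities are normalized by the maximum IC.
    """
    dags = list(dags)
    if not dags:
        raise ValueError("empty DAG collection")
    counts: dict[str, int] = {}
    for dag in dags:
        for term in dag.nodes:
            counts[term] = counts.get(term, 0) + 1
    tn = len(dags)
    log_base = math.log(base)
    ic = {t: -math.log(n / tn) / log_base for t, n in counts.items()}
    return ICTable(ic=ic, n_dag=counts, tn_dag=tn)


def compute_fuzzy_density(
    ic_table: ICTable,
    dag: DiseaseDAG,
    cap: float = DEFAULT_DENSITY_CAP,
) -> FuzzyDensitySet:
    """Normalize a DAG's term ICs into fuzzy densities in (0, cap].

    Raw density is ``IC(t) / max IC`` over the whole corpus; the result is
    scaled by ``cap`` and zero-density (universal) terms are pruned.
    """
    if not 0 < cap <= 1:
        raise ValueError(f"cap must be in (0, 1], got {cap}")
    max_ic = max(ic_table.ic.values(), default=0.0)
    if max_ic <= 0:
        raise ValueError(
            "all terms have zero information content; the corpus has a single "
            "effective DAG, so densities are undefined"
        )
    densities = {}
    for term in dag.nodes:
        try:
            ic = ic_table.ic[term]
        except KeyError:
            raise ValueError(f"term {term!r} has no IC entry") from None
        if ic > 0:
            densities[term] = cap * ic / max_ic
    return FuzzyDensitySet(disease_id=dag.disease_id, densities=densities)


def _lambda_residual(lam: float, dens: np.ndarray) -> float:
    return float(np.prod(1.0 + lam * dens) - (1.0 + lam))


def solve_lambda(densities, tol: float = LAMBDA_TOL) -> float:
    """Solve ``1 + lam = prod(1 + lam * g_i)`` for the non-trivial root.

    lam = 0 always solves the equation; the measure-defining root is the
    other one, negative when ``sum(g) > 1`` and positive when ``sum(g) < 1``.
    When the densities sum to 1 (the additive case, within ``tol``) or the
    set is a singleton the unique consistent answer is 0.  Root finding is
    bracketed (Brent) for robustness, never an unbracketed Newton.
    """
    dens = np.asarray(list(densities), dtype=float)
    if dens.size == 0:
        raise ValueError("empty density set")
    if np.any(dens <= 0) or np.any(dens >= 1):
        raise ValueError("densities must lie strictly in (0, 1)")
    if dens.size == 1:
        return 0.0
    s = float(dens.sum())
    if abs(s - 1.0) <= tol:
        return 0.0

    f = lambda lam: _lambda_residual(lam, dens)  # noqa: E731

    if s > 1.0:
        # Root in (-1, 0): f(-1+eps) > 0, f just left of 0 is negative.
        lo = -1.0 + 1e-12
        if f(lo) < 0:
            # The root is within 1e-12 of -1 (prod(1-g) underflows the
            # offset); the endpoint's own residual is below 1e-12 there.
            return lo
        hi = -1e-9
        while f(hi) >= 0 and hi < -1e-300:
            hi *= 1e-3
        if f(hi) >= 0:
            return 0.0
    else:
        # Root in (0, inf): f just right of 0 is negative, f -> +inf.
        lo = 1e-9
        while f(lo) >= 0 and lo > 1e-300:
            lo *= 1e-3
        if f(lo) >= 0:
            # Degenerate: the root is closer to 0 than the bracket floor.
            return 0.0
        hi = 1.0
        while f(hi) <= 0:
            hi *= 2.0
            if hi > 1e12:
                raise RuntimeError("lambda bracket expansion failed")
    root = brentq(f, lo, hi, xtol=tol, rtol=8.9e-16, maxiter=200)
    # Newton polish in extended precision: for large roots the double
    # product and 1 + lam agree to ~1e5 ulp, so the residual floor of a
    # float64 evaluation would sit near 1e-10.
    dl = np.asarray(dens, dtype=np.longdouble)
    x = np.longdouble(root)
    for _ in range(3):
        factors = 1 + x * dl
        prod = factors.prod()
        resid = prod - 1 - x
        deriv = prod * (dl / factors).sum() - 1
        if deriv == 0:
            break
        step = resid / deriv
        if x - step <= -1:
            break
        x -= step
        if abs(step) < np.longdouble(1e-25) * max(1, abs(x)):
            break
    root = float(x)
    return root


def sugeno_measure(subset, lam: float) -> float:
    """Sugeno measure of a density subset under a given lambda.

    Evaluated by the defining recursion
    ``g(T) = FD(t) + g(T') + lam * FD(t) * g(T')`` with t in T, which is
    order-independent; the empty set measures 0 and a singleton measures its
    only element.
    """
    if lam <= -1:
        raise ValueError(f"lambda must exceed -1, got {lam}")
    acc = 0.0
    for d in subset:
        if not 0 < d < 1:
            raise ValueError(f"density {d} outside (0, 1)")
        acc = d + acc + lam * d * acc
    return acc


def solve_density_set(ds: FuzzyDensitySet) -> FuzzyDensitySet:
    """Attach the solved lambda to a density set (no-op on empty sets)."""
    if ds.densities:
        ds.lam = solve_lambda(ds.densities.values())
    else:
        ds.lam = 0.0
    return ds


def density_sets_from_dags(
    dags: dict[str, DiseaseDAG],
    cap: float = DEFAULT_DENSITY_CAP,
    base: float = math.e,
) -> dict[str, FuzzyDensitySet]:
    """Full step 1-3 pipeline: IC, densities and lambda for every disease."""
    ic = compute_ic(dags.values(), base=base)
    return {
        did: solve_density_set(compute_fuzzy_density(ic, dag, cap=cap))
        for did, dag in dags.items()
    }


def disease_semantic_similarity(a: FuzzyDensitySet, b: FuzzyDensitySet) -> float:
    """Average the two Sugeno measures of the shared term set.

    The shared terms carry identical, globally normalized densities in both
    sets; each disease evaluates the shared set under its own lambda.  An
    empty intersection scores 0.
    """
    if a.lam is None or b.lam is None:
        raise ValueError("lambda must be solved before computing similarity")
    common = a.densities.keys() & b.densities.keys()
    if not common:
        return 0.0
    dens = [a.densities[t] for t in common]
    ga = sugeno_measure(dens, a.lam)
    gb = sugeno_measure(dens, b.lam)
    return 0.5 * (ga + gb)


def build_disease_similarity_matrix(density_sets) -> DiseaseSimilarityMatrix:
    """Assemble the symmetric disease similarity matrix FS.

    Each unordered pair is computed once; the diagonal of a disease with a
    nonempty density set is pinned to 1 (what the full-set measure equals by
    construction, without solver-tolerance noise).
    """
    sets = list(density_sets)
    if not sets:
        raise ValueError("need at least one disease")
    n = len(sets)
    fs = np.zeros((n, n))
    for i in range(n):
        fs[i, i] = 1.0 if sets[i].densities else 0.0
        for j in range(i + 1, n):
            fs[i, j] = fs[j, i] = disease_semantic_similarity(sets[i], sets[j])
    np.clip(fs, 0.0, 1.0, out=fs)
    return DiseaseSimilarityMatrix(
        disease_ids=[s.disease_id for s in sets], values=fs
    )
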