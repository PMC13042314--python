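"""LTR retrotransposon insertion-age dating and subgenome enrichment.

An LTR retrotransposon inserts with two identical long terminal repeats;
they then diverge neutrally, so the corrected distance d between the 5'
and 3' LTR dates the insertion: T = d / (2 mu). Distances are
Jukes-Cantor corrected by default (d = -(3/4) ln(1 - 4p/3)); a Kimura
two-parameter correction is available behind a flag. Per-family,
per-subgenome enrichment uses the hypergeometric tail (equivalent to a
label-permutation null) with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from .seqs import as_array

DEFAULT_MU = 1.3e-8  # substitutions/site/year, typical grass rate


@dataclass
class LtrElement:
    """One LTR retrotransposon copy with both terminal repeats."""

    element_id: str
    family: str
    chromosome: str
    ltr5: str
    ltr3: str

    def __post_init__(self) -> None:
        if not self.ltr5 or not self.ltr3:
            raise ValueError("both LTR sequences must be non-empty")


@dataclass
class AgeEstimate:
    p_distance: float
    d: float  # corrected substitutions/site
    age_years: float
    mu: float


def ltr_p_distance(ltr5: str, ltr3: str) -> float:
    """Mismatches per aligned non-gap column between the two LTRs.

    Equal-length sequences are compared site-by-site; otherwise they are
    globally aligned first (unit-cost edit alignment) and gap columns are
    excluded.
    """
    if not ltr5 or not ltr3:
        raise ValueError("empty LTR sequence")
    if len(ltr5) == len(ltr3):
        a = as_array(ltr5)
        b = as_array(ltr3)
        ok = (a < 4) & (b < 4)
        n = int(ok.sum())
        if n == 0:
            raise ValueError("no comparable columns")
        return float(np.count_nonzero(a[ok] != b[ok])) / n
    res = edlib.align(ltr5, ltr3, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, ltr5, ltr3)
    qa, ta = nice["query_aligned"], nice["target_aligned"]
    pairs = [(x, y) for x, y in zip(qa, ta) if x != "-" and y != "-"]
    if not pairs:
        raise ValueError("no comparable columns after alignment")
    mism = sum(1 for x, y in pairs if x != y)
    return mism / len(pairs)


def jc_correct(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3)."""
    if not (0.0 <= p < 0.75):
        raise ValueError("p-distance saturated (must be in [0, 0.75))")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def k2p_correct(ltr5: str, ltr3: str) -> float:
    """Kimura two-parameter distance from transition/transversion counts."""
    a = as_array(ltr5)
    b = as_array(ltr3)
    if a.size != b.size:
        raise ValueError("K2P correction requires pre-aligned equal-length LTRs")
    ok = (a < 4) & (b < 4)
    a, b = a[ok], b[ok]
    if a.size == 0:
        raise ValueError("no comparable columns")
    diff = a != b
    # purine A(0)/G(2), pyrimidine C(1)/T(3): transition iff same parity
    transitions = diff & ((a % 2) == (b % 2))
    P = transitions.sum() / a.size
    Q = (diff.sum() - transitions.sum()) / a.size
    inner1 = 1.0 - 2.0 * P - Q
    inner2 = 1.0 - 2.0 * Q
    if inner1 <= 0 or inner2 <= 0:
        raise ValueError("K2P distance saturated")
    return -0.5 * math.log(inner1) - 0.25 * math.log(inner2)


def insertion_age(d: float, mu: float = DEFAULT_MU) -> float:
    """T = d / (2 mu), in years."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    return d / (2.0 * mu)


def date_element(element: LtrElement, mu: float = DEFAULT_MU, model: str = "jc") -> AgeEstimate:
    """Full dating of one element: p-distance, correction, age."""
    p = ltr_p_distance(element.ltr5, element.ltr3)
    if model == "jc":
        d = jc_correct(p)
    elif model == "k2p":
        d = k2p_correct(element.ltr5, element.ltr3)
    else:
        raise ValueError("model must be 'jc' or 'k2p'")
    return AgeEstimate(p_distance=p, d=d, age_years=insertion_age(d, mu), mu=mu)


@dataclass
class AgeProfile:
    """Binned insertion-age distributions per subgenome."""

    ages: dict[str, np.ndarray]  # subgenome -> ages in years
    bin_edges: np.ndarray
    histograms: dict[str, np.ndarray]
    summary: pd.DataFrame  # subgenome, n, mean/median age


def subgenome_age_profile(
    elements: list[LtrElement],
    assignment: dict[str, str],
    mu: float = DEFAULT_MU,
    bins: int = 20,
    model: str = "jc",
) -> AgeProfile:
    """Insertion-age histograms and summaries per subgenome.

    Every element's chromosome must be labelled in ``assignment``; a
    subgenome with no elements simply yields an empty profile.
    """
    ages: dict[str, list[float]] = {sg: [] for sg in sorted(set(assignment.values()))}
    for el in elements:
        if el.chromosome not in assignment:
            raise KeyError(f"chromosome {el.chromosome} not labelled")
        est = date_element(el, mu=mu, model=model)
        ages[assignment[el.chromosome]].append(est.age_years)
    arr = {sg: np.asarray(v, dtype=float) for sg, v in ages.items()}
    all_ages = np.concatenate([v for v in arr.values() if v.size]) if any(
        v.size for v in arr.values()
    ) else np.array([0.0])
    edges = np.histogram_bin_edges(all_ages, bins=bins)
    hists = {sg: np.histogram(v, bins=edges)[0] for sg, v in arr.items()}
    rows = []
    for sg, v in arr.items():
        rows.append(
            {
                "subgenome": sg,
                "n_elements": v.size,
                "mean_age": float(v.mean()) if v.size else np.nan,
                "median_age": float(np.median(v)) if v.size else np.nan,
            }
        )
    return AgeProfile(
        ages=arr, bin_edges=edges, histograms=hists, summary=pd.DataFrame(rows)
    )


def family_enrichment(
    elements: list[LtrElement],
    assignment: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of repeat families per subgenome.

    For a family with n members of which k lie on subgenome s, the raw
    p-value is P(X >= k) with X ~ Hypergeom(population = all elements,
    successes = all elements on s, draws = n) — the exact tail of the
    label-permutation null. Benjamini-Hochberg adjusted across all
    family x subgenome tests.
    """
    if not elements:
        raise ValueError("need at least one element")
    for el in elements:
        if el.chromosome not in assignment:
            raise KeyError(f"chromosome {el.chromosome} not labelled")
    total = len(elements)
    subgenomes = sorted(set(assignment.values()))
    per_sub = {
        sg: sum(1 for el in elements if assignment[el.chromosome] == sg)
        for sg in subgenomes
    }
    families = sorted({el.family for el in elements})
    rows = []
    for fam in families:
        fam_el = [el for el in elements if el.family == fam]
        n = len(fam_el)
        for sg in subgenomes:
            k = sum(1 for el in fam_el if assignment[el.chromosome] == sg)
            p = float(hypergeom.sf(k - 1, total, per_sub[sg], n))
            rows.append(
                {
                    "family": fam,
                    "subgenome": sg,
                    "k": k,
                    "n_family": n,
                    "subgenome_elements": per_sub[sg],
                    "p_raw": p,
                }
            )
    df = pd.DataFrame(rows)
    df["p_adj"] = false_discovery_control(df["p_raw"].to_numpy(), method="bh")
    df["significant"] = df["p_adj"] < alpha
    return df


def elements_from_truth(polyploid: dict, truth) -> list[LtrElement]:
    """Harvest LTR elements of a simulated genome from its ground truth.

    Slices both LTRs out of each composed chromosome at the recorded
    insertion coordinates (so the sequences carry haplotype-level mutation
    on top of the age signal).
    """
    from .seqs import decode

    out = []
    i = 0
    for seq_id, recs in truth.repeats_by_seq.items():
        arr = as_array(polyploid[seq_id])
        for rec in recs:
            i += 1
            out.append(
                LtrElement(
                    element_id=f"{seq_id}_{rec.family}_{i:05d}",
                    family=rec.family,
                    chromosome=seq_id,
                    ltr5=decode(arr[rec.start : rec.start + rec.ltr_length]),
                    ltr3=decode(arr[rec.end - rec.ltr_length : rec.end]),
                )
            )
    return out


def elements_table(elements: list[LtrElement], mu: float = DEFAULT_MU) -> pd.DataFrame:
    """Per-element dating table (id, family, chromosome, p, d, age)."""
    rows = []
    for el in elements:
        est = date_element(el, mu=mu)
        rows.append(
            {
                "element_id": el.element_id,
                "family": el.family,
                "chromosome": el.chromosome,
                "p_distance": est.p_distance,
                "jc_distance": est.d,
                "age_years": est.age_years,
            }
        )
    return pd.DataFrame(rows)
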