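"""Stage 1: sex-biased drug-adverse-event pair detection.

From filtered case reports, one 2x2 contingency table is built per
drug-event pair:

    A = exposed females with the event      B = exposed females without it
    C = exposed males with the event        D = exposed males without it

The reporting odds ratio ROR = (A*D)/(B*C) compares the odds of the event
among exposed females with the odds among exposed males; log2(ROR) > 0
indicates female bias. Pairs pass report-count filters, get a Fisher exact
p-value and BH adjustment, and are labelled female-/male-biased when
|log2 ROR| > 1 and adjusted p < 0.05.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import TermHierarchy
from .stats import bh_adjust, fisher_exact_2x2, hypergeom_overlap_test

log = logging.getLogger(__name__)

__all__ = ["filter_cases", "map_terms", "build_contingency",
           "apply_report_filters", "score_pairs", "overlap_summary"]

DEFAULT_QUALIFICATIONS = frozenset({"1", "2", "3"})


def filter_cases(cases: pd.DataFrame, country: str = "US",
                 qualifications: frozenset = DEFAULT_QUALIFICATIONS
                 ) -> pd.DataFrame:
    """Keep analyzable reports: matching country, health-professional
    reporter, known sex, at least one drug and one event; for duplicated
    case ids only the newest report is retained (unknown dates sort oldest).
    """
    kept = cases[
        (cases["country"] == country)
        & cases["qualification"].isin(qualifications)
        & cases["sex"].isin(["male", "female"])
        & (cases["drugs"].map(len) > 0)
        & (cases["events"].map(len) > 0)
    ]
    # newest report per case id; stable sort keeps input order among ties
    kept = kept.sort_values("report_date", kind="stable", na_position="first")
    kept = kept.drop_duplicates("case_id", keep="last")
    kept = kept.sort_index()
    log.info("filter_cases: %d of %d reports retained", len(kept), len(cases))
    return kept.reset_index(drop=True)


def map_terms(cases: pd.DataFrame, hierarchy: TermHierarchy) -> pd.DataFrame:
    """Map every event term to its preferred term.

    Terms without a mapping are passed through unchanged (and logged);
    lower-level terms collapsing onto one preferred term within a case merge
    into a single event.
    """
    mapping = hierarchy.lower_to_preferred
    unmapped = set()

    def _map(events: frozenset) -> frozenset:
        out = set()
        for e in events:
            if e in mapping:
                out.add(mapping[e])
            else:
                if e not in hierarchy.preferred_to_soc:
                    unmapped.add(e)
                out.add(e)
        return frozenset(out)

    out = cases.copy()
    out["events"] = out["events"].map(_map)
    if unmapped:
        log.warning("map_terms: %d terms not covered by the hierarchy, "
                    "passed through unchanged", len(unmapped))
    return out


def build_contingency(cases: pd.DataFrame) -> pd.DataFrame:
    """One contingency table per (drug, event) pair.

    A case contributes once per (drug, event); the B/D denominators are
    case-level (a case exposed to a drug counts once regardless of how many
    other events it lists). Pairs never co-reported have A = C = 0 and are
    removed by the report filters.
    """
    idx = np.arange(len(cases))
    n_drugs = cases["drugs"].map(len).to_numpy()
    n_events = cases["events"].map(len).to_numpy()
    case_drug = pd.DataFrame({
        "case": np.repeat(idx, n_drugs),
        "drug": [d for ds in cases["drugs"] for d in sorted(ds)],
    })
    case_event = pd.DataFrame({
        "case": np.repeat(idx, n_events),
        "event": [e for es in cases["events"] for e in sorted(es)],
    })
    female = (cases["sex"] == "female").to_numpy()
    case_drug["female"] = female[case_drug["case"]]

    exposed = case_drug.groupby(["drug", "female"]).size().unstack(fill_value=0)
    exposed_f = exposed.get(True, pd.Series(0, index=exposed.index))
    exposed_m = exposed.get(False, pd.Series(0, index=exposed.index))

    co = case_drug.merge(case_event, on="case")
    with_event = co.groupby(["drug", "event", "female"]).size().unstack(fill_value=0)
    a = with_event.get(True, pd.Series(0, index=with_event.index))
    c = with_event.get(False, pd.Series(0, index=with_event.index))

    drugs = exposed.index
    events = sorted(case_event["event"].unique())
    full = pd.MultiIndex.from_product([drugs, events], names=["drug", "event"])
    a = a.reindex(full, fill_value=0)
    c = c.reindex(full, fill_value=0)
    tables = pd.DataFrame({"A": a, "C": c}).reset_index()
    tables["B"] = exposed_f.reindex(tables["drug"]).to_numpy() - tables["A"]
    tables["D"] = exposed_m.reindex(tables["drug"]).to_numpy() - tables["C"]
    return tables[["drug", "event", "A", "B", "C", "D"]].astype(
        {"A": int, "B": int, "C": int, "D": int})


def apply_report_filters(tables: pd.DataFrame,
                         min_one_sex: int = 30,
                         min_both_sexes: int = 50,
                         min_drug_total: int = 1000,
                         min_per_sex: int = 5) -> pd.DataFrame:
    """Report-count filters keeping commonly used drug-event pairs.

    Retained iff (A >= 30 or C >= 30) and A + C >= 50 and
    A + B + C + D >= 1000 and (A > 5 and C > 5). Idempotent and
    order-independent (each rule is a pure row predicate).
    """
    a, b, c, d = (tables[k] for k in "ABCD")
    keep = (((a >= min_one_sex) | (c >= min_one_sex))
            & (a + c >= min_both_sexes)
            & (a + b + c + d >= min_drug_total)
            & (a > min_per_sex) & (c > min_per_sex))
    return tables[keep].reset_index(drop=True)


def score_pairs(tables: pd.DataFrame, alpha: float = 0.05,
                logror_cut: float = 1.0,
                fisher_alternative: str = "two-sided") -> pd.DataFrame:
    """ROR, log2 ROR, Fisher p, BH-adjusted p and bias label per pair.

    When any cell is zero, the Haldane-Anscombe 0.5 correction is applied to
    all four cells for the ROR only (the exact p-value is unaffected); such
    rows are flagged in ``zero_cell``.
    """
    if tables.empty:
        out = tables.copy()
        for col in ("ror", "log2ror", "p", "p_adj"):
            out[col] = pd.Series(dtype=float)
        out["bias"] = pd.Series(dtype=object)
        out["zero_cell"] = pd.Series(dtype=bool)
        return out
    out = tables.copy().reset_index(drop=True)
    a = out["A"].to_numpy(float)
    b = out["B"].to_numpy(float)
    c = out["C"].to_numpy(float)
    d = out["D"].to_numpy(float)
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    aa, bb, cc, dd = (x + np.where(zero, 0.5, 0.0) for x in (a, b, c, d))
    out["ror"] = (aa * dd) / (bb * cc)
    out["log2ror"] = np.log2(out["ror"])
    out["zero_cell"] = zero
    out["p"] = [
        fisher_exact_2x2(int(r.A), int(r.B), int(r.C), int(r.D),
                         alternative=fisher_alternative).p_value
        for r in out.itertuples()
    ]
    out["p_adj"] = bh_adjust(out["p"].tolist()).values
    sig = out["p_adj"] < alpha
    out["bias"] = np.select(
        [sig & (out["log2ror"] > logror_cut), sig & (out["log2ror"] < -logror_cut)],
        ["female", "male"], default="none")
    return out


def overlap_summary(results: pd.DataFrame, universe: str = "tested") -> dict:
    """Overlap of drugs and of events between female- and male-biased pairs.

    The hypergeometric universe defaults to all drugs (resp. events)
    appearing in any tested pair; ``universe="biased"`` restricts it to
    entities from biased pairs only.
    """
    summary = {}
    for col in ("drug", "event"):
        fset = set(results.loc[results["bias"] == "female", col])
        mset = set(results.loc[results["bias"] == "male", col])
        if universe == "tested":
            uni = set(results[col])
        else:
            uni = fset | mset
        shared = fset & mset
        test = hypergeom_overlap_test(len(uni), len(fset), len(mset), len(shared))
        summary[col] = {
            "n_female": len(fset), "n_male": len(mset),
            "n_shared": len(shared), "n_universe": len(uni),
            "p": test.p_value,
        }
    summary["n_pairs_tested"] = int(len(results))
    summary["n_pairs_female"] = int((results["bias"] == "female").sum())
    summary["n_pairs_male"] = int((results["bias"] == "male").sum())
    return summary
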