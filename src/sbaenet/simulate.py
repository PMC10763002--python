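"""Synthetic pipeline inputs with planted, recoverable ground truth.

Three generators emulate the statistical structure of the real inputs:

* ``simulate_cases`` — spontaneous case reports. Each case gets a sex, one or
  more drugs from a power-law popularity distribution, and per exposed drug a
  Bernoulli draw for every adverse-event term. A planted sex-biased pair
  multiplies the event odds by 2^(r/2) among exposed females and 2^(-r/2)
  among exposed males, so the reporting odds ratio equals 2^r in expectation.
* ``simulate_annotations`` — drug -> target/enzyme gene annotations with
  features planted at an elevated frequency among a designated drug set.
* ``simulate_expression`` — negative-binomial counts around a log-linear
  model: gene baseline (spanning ~4 orders of magnitude) + a planted sex
  effect + latent-TF-activity contributions for genes with a motif-prior
  edge. A differential-regulation spec scales a TF->gene coupling in one sex
  only, planting sex-differential co-regulation consistent with the motif
  prior.

All generators are pure functions of (parameters, seed) and return a
``SimulationTruth`` recording every planted object.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionData

__all__ = ["SimulationTruth", "simulate_cases", "simulate_annotations",
           "simulate_expression", "drug_id", "event_id", "gene_id", "tf_id"]


def drug_id(i: int) -> str:
    return f"D{i:04d}"


def event_id(i: int) -> str:
    return f"E{i:03d}"


def gene_id(i: int) -> str:
    return f"G{i:04d}"


def tf_id(i: int) -> str:
    return f"TF{i:03d}"


@dataclass
class SimulationTruth:
    """Record of everything planted by a generator run."""

    planted_pairs: list = field(default_factory=list)
    planted_features: dict = field(default_factory=dict)
    planted_sex_biased_genes: dict = field(default_factory=dict)
    planted_diff_edges: list = field(default_factory=list)
    seeds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _odds_to_prob(odds: np.ndarray) -> np.ndarray:
    return odds / (1.0 + odds)


def simulate_cases(n_cases: int = 50_000,
                   drug_catalog: int = 40,
                   event_catalog: int = 25,
                   baseline_rate: float = 0.04,
                   planted: list | None = None,
                   sex_ratio: float = 0.5,
                   seed: int = 0,
                   mean_extra_drugs: float = 0.5,
                   popularity_exponent: float = 0.6,
                   country: str = "US") -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate a case-report table with planted sex-biased drug-event pairs.

    Parameters
    ----------
    planted
        Each entry: ``{"drug": int | str, "event": int | str,
        "log2ror": float, "exposure": int (optional)}``. ``exposure`` sets
        the drug's expected number of exposed cases by overriding its
        popularity weight; the event odds among exposed cases are tilted so
        the female/male reporting odds ratio equals ``2**log2ror``.

    Defaults emulate a mid-sized national pharmacovigilance extract: 50,000
    usable reports over a 40-drug, 25-term vocabulary with a 4% per-term
    reporting rate, which leaves on the order of 500 drug-event pairs
    passing the downstream report-count filters.
    """
    if not (0.0 < baseline_rate < 1.0):
        raise ValueError("baseline_rate must be in (0, 1)")
    if not (0.0 < sex_ratio < 1.0):
        raise ValueError("sex_ratio must be in (0, 1)")
    planted = planted or []
    rng = np.random.default_rng(seed)

    def _drug_index(d):
        idx = int(d[1:]) if isinstance(d, str) else int(d)
        if not 0 <= idx < drug_catalog:
            raise ValueError(f"planted drug {d!r} outside catalog")
        return idx

    def _event_index(e):
        idx = int(e[1:]) if isinstance(e, str) else int(e)
        if not 0 <= idx < event_catalog:
            raise ValueError(f"planted event {e!r} outside catalog")
        return idx

    # drug popularity: power law, optionally overridden for planted drugs so
    # their expected exposure is controlled
    weights = (np.arange(drug_catalog) + 1.0) ** (-popularity_exponent)
    total_exposures = n_cases * (1.0 + mean_extra_drugs)
    fixed = {}
    for spec in planted:
        if "exposure" in spec and spec["exposure"] is not None:
            fixed[_drug_index(spec["drug"])] = spec["exposure"] / total_exposures
    free = np.array([i not in fixed for i in range(drug_catalog)])
    probs = np.zeros(drug_catalog)
    fixed_mass = sum(fixed.values())
    if fixed_mass >= 1.0:
        raise ValueError("planted exposures exceed the total exposure budget")
    probs[~free] = [fixed[i] for i in range(drug_catalog) if i in fixed]
    probs[free] = weights[free] / weights[free].sum() * (1.0 - fixed_mass)

    # per-case sex and drug exposures
    sex_female = rng.random(n_cases) < sex_ratio
    n_drugs = 1 + rng.poisson(mean_extra_drugs, size=n_cases)
    case_of_exposure = np.repeat(np.arange(n_cases), n_drugs)
    drug_of_exposure = rng.choice(drug_catalog, size=case_of_exposure.size, p=probs)
    # set semantics: a case lists each drug at most once
    key = case_of_exposure.astype(np.int64) * drug_catalog + drug_of_exposure
    keep = np.zeros(key.size, dtype=bool)
    keep[np.unique(key, return_index=True)[1]] = True
    case_of_exposure = case_of_exposure[keep]
    drug_of_exposure = drug_of_exposure[keep]

    # baseline event draws, one Bernoulli per (exposure, event term), OR-ed
    # into a dense case x event membership matrix
    truth = SimulationTruth(seeds={"cases": seed})
    fired = rng.random((case_of_exposure.size, event_catalog)) < baseline_rate
    membership = np.zeros((n_cases, event_catalog), dtype=bool)
    np.logical_or.at(membership, case_of_exposure, fired)

    # planted pairs: among cases exposed to the planted drug, the planted
    # event's membership is a single tilted Bernoulli at case level (it
    # overrides baseline contributions from co-reported drugs, keeping the
    # female/male odds ratio exactly 2^r in expectation)
    base_odds = baseline_rate / (1.0 - baseline_rate)
    planted_events = set()
    for spec in planted:
        di, ei = _drug_index(spec["drug"]), _event_index(spec["event"])
        r = float(spec["log2ror"])
        p_male = _odds_to_prob(base_odds * 2.0 ** (-r / 2.0))
        p_female = _odds_to_prob(base_odds * 2.0 ** (r / 2.0))
        exposed = np.unique(case_of_exposure[drug_of_exposure == di])
        p_case = np.where(sex_female[exposed], p_female, p_male)
        membership[exposed, ei] = rng.random(exposed.size) < p_case
        planted_events.add(ei)
        truth.planted_pairs.append({"drug": drug_id(di), "event": event_id(ei),
                                    "true_log2ror": r,
                                    "exposure": spec.get("exposure")})

    # every case reports at least one event term; fill-ins avoid planted
    # event columns so they stay exactly at their tilted rates
    silent = np.nonzero(~membership.any(axis=1))[0]
    if silent.size:
        pool = np.array(sorted(set(range(event_catalog)) - planted_events))
        if pool.size == 0:
            pool = np.arange(event_catalog)
        membership[silent, rng.choice(pool, size=silent.size)] = True

    ev_case, ev_event = np.nonzero(membership)

    drug_lists = pd.Series(
        [drug_id(d) for d in drug_of_exposure], dtype=object
    ).groupby(case_of_exposure).agg(frozenset)
    event_lists = pd.Series(
        [event_id(e) for e in ev_event], dtype=object
    ).groupby(ev_case).agg(frozenset)

    dates = (pd.Timestamp("2015-01-01")
             + pd.to_timedelta(rng.integers(0, 2922, size=n_cases), unit="D"))
    cases = pd.DataFrame({
        "case_id": [f"C{i:07d}" for i in range(n_cases)],
        "report_date": dates,
        "sex": np.where(sex_female, "female", "male"),
        "country": country,
        "qualification": rng.choice(["1", "2", "3"], size=n_cases),
        "drugs": drug_lists.reindex(range(n_cases)).values,
        "events": event_lists.reindex(range(n_cases)).values,
    })
    return cases, truth


def simulate_annotations(n_drugs: int = 400,
                         n_features: int = 50,
                         background_freq: float = 0.05,
                         planted_features: dict | None = None,
                         sbae_drug_ids: set | None = None,
                         seed: int = 0,
                         field_name: str = "targets",
                         feature_names: list | None = None
                         ) -> tuple[dict, SimulationTruth]:
    """Generate drug annotations with features enriched in a drug set.

    ``planted_features`` maps a feature gene symbol to the fraction of
    ``sbae_drug_ids`` annotated with it; every other (drug, feature)
    membership is Bernoulli(``background_freq``). Both the ``targets`` and
    ``enzymes`` fields are populated; planting applies to ``field_name``.
    """
    planted_features = planted_features or {}
    sbae_drug_ids = set(sbae_drug_ids or ())
    for f, frac in planted_features.items():
        if frac <= background_freq:
            raise ValueError(
                f"planted frequency for {f!r} must exceed the background")
    rng = np.random.default_rng(seed)
    drugs = [drug_id(i) for i in range(n_drugs)]
    unknown = sbae_drug_ids - set(drugs)
    if unknown:
        raise ValueError(f"sbae drugs not in catalog: {sorted(unknown)[:5]}")
    if feature_names is not None:
        if len(feature_names) != n_features:
            raise ValueError("feature_names length must equal n_features")
        features = list(feature_names)
    else:
        features = [f"FEAT{i:03d}" for i in range(n_features)]
    planted_only = [f for f in planted_features if f not in features]

    membership = {f: {} for f in ("targets", "enzymes")}
    for fld in ("targets", "enzymes"):
        mat = rng.random((n_drugs, n_features)) < background_freq
        for j, feat in enumerate(features):
            membership[fld][feat] = {drugs[i] for i in np.nonzero(mat[:, j])[0]}
    for feat, frac in planted_features.items():
        hits = membership[field_name].setdefault(feat, set())
        if feat in planted_only:  # background occurrences outside the SBAE set
            bg = rng.random(n_drugs) < background_freq
            hits |= {drugs[i] for i in np.nonzero(bg)[0] if drugs[i] not in sbae_drug_ids}
        else:
            hits -= sbae_drug_ids
        planted_hits = rng.random(len(sbae_drug_ids)) < frac
        hits |= {d for d, h in zip(sorted(sbae_drug_ids), planted_hits) if h}

    annotations = {
        d: {fld: frozenset(f for f, ds in membership[fld].items() if d in ds)
            for fld in ("targets", "enzymes")}
        for d in drugs
    }
    for d in annotations:
        annotations[d]["transporters"] = frozenset()
        annotations[d]["carriers"] = frozenset()
    truth = SimulationTruth(planted_features=dict(planted_features),
                            seeds={"annotations": seed})
    return annotations, truth


def simulate_expression(n_genes: int = 200,
                        n_tfs: int = 20,
                        samples_per_sex: int = 60,
                        nb_dispersion: float = 0.1,
                        sex_biased_spec: list | None = None,
                        diff_regulation_spec: list | None = None,
                        motif_density: float = 0.10,
                        ppi_density: float = 0.20,
                        seed: int = 0,
                        tissue: str = "liver",
                        base_coupling: float = 0.25,
                        tf_activity_coupling: float = 0.5,
                        rin_range: tuple = (6.0, 10.0),
                        ischemic_range: tuple = (60.0, 1200.0)
                        ) -> tuple[ExpressionData, pd.DataFrame, pd.DataFrame,
                                   SimulationTruth]:
    """Generate per-sex negative-binomial expression plus network priors.

    Returns (expression, motif prior edge list, TF-TF interaction edge list,
    truth). The expression matrix contains the ``n_tfs`` TF genes as rows in
    addition to the ``n_genes`` target genes, so TF expression is available
    for correlation-based edge typing.

    * ``sex_biased_spec``: list of ``{"gene": id, "log2fc": float}``;
      positive log2fc means higher female expression (split symmetrically
      between the sexes).
    * ``diff_regulation_spec``: list of ``{"tf": id, "gene": id, "sex":
      "female" | "male", "boost": float}``; the TF->gene activity coupling is
      multiplied by ``boost`` in that sex only, and the edge is forced into
      the motif prior.
    """
    if samples_per_sex < 5:
        raise ValueError("need at least 5 samples per sex "
                         "(tissue-inclusion rule)")
    sex_biased_spec = sex_biased_spec or []
    diff_regulation_spec = diff_regulation_spec or []
    rng = np.random.default_rng(seed)

    genes = [gene_id(i) for i in range(n_genes)]
    tfs = [tf_id(i) for i in range(n_tfs)]
    all_rows = tfs + genes
    n_samples = 2 * samples_per_sex
    sexes = np.array(["female"] * samples_per_sex + ["male"] * samples_per_sex)

    # motif prior: Bernoulli edges, planted differential edges forced in
    motif = rng.random((n_tfs, n_genes)) < motif_density
    truth = SimulationTruth(seeds={"expression": seed})
    gene_idx = {g: i for i, g in enumerate(genes)}
    tf_idx = {t: i for i, t in enumerate(tfs)}
    for spec in diff_regulation_spec:
        ti, gi = tf_idx[spec["tf"]], gene_idx[spec["gene"]]
        motif[ti, gi] = True
        truth.planted_diff_edges.append({"tf": spec["tf"], "gene": spec["gene"],
                                         "sex": spec["sex"],
                                         "boost": float(spec["boost"])})

    # couplings per sex: base for every motif edge, boosted in one sex
    coupling = {s: motif.astype(float) * base_coupling for s in ("female", "male")}
    for spec in diff_regulation_spec:
        ti, gi = tf_idx[spec["tf"]], gene_idx[spec["gene"]]
        coupling[spec["sex"]][ti, gi] *= float(spec["boost"])

    # log2 mean model
    baseline = rng.uniform(np.log2(0.5), np.log2(5000.0), size=len(all_rows))
    sex_effect = np.zeros(len(all_rows))
    row_idx = {g: i for i, g in enumerate(all_rows)}
    for spec in sex_biased_spec:
        sex_effect[row_idx[spec["gene"]]] = float(spec["log2fc"])
        truth.planted_sex_biased_genes[spec["gene"]] = float(spec["log2fc"])

    activity = rng.normal(0.0, 1.0, size=(n_tfs, n_samples))
    log2_mu = np.tile(baseline[:, None], (1, n_samples)).astype(float)
    log2_mu += np.where(sexes == "female", 0.5, -0.5)[None, :] * sex_effect[:, None]
    log2_mu[:n_tfs, :] += tf_activity_coupling * activity
    for s in ("female", "male"):
        cols = sexes == s
        log2_mu[n_tfs:, cols] += coupling[s].T @ activity[:, cols]

    depth = rng.uniform(0.75, 1.5, size=n_samples)  # <= 2-fold library variation
    mu = np.maximum(2.0 ** log2_mu * depth[None, :], 1e-8)
    shape = 1.0 / nb_dispersion
    counts = rng.poisson(rng.gamma(shape, mu / shape))

    samples = pd.DataFrame({
        "sample_id": [f"S{i:04d}" for i in range(n_samples)],
        "subject_id": [f"SUBJ{i:04d}" for i in range(n_samples)],
        "sex": sexes,
        "tissue": tissue,
        "rin": rng.uniform(*rin_range, size=n_samples),
        "ischemic_time": rng.uniform(*ischemic_range, size=n_samples),
        "age": rng.integers(20, 71, size=n_samples),
    }).set_index("sample_id")
    expr = ExpressionData(
        counts=pd.DataFrame(counts, index=all_rows, columns=samples.index),
        samples=samples)

    ti_, gi_ = np.nonzero(motif)
    motif_edges = pd.DataFrame({"source": [tfs[i] for i in ti_],
                                "target": [genes[j] for j in gi_],
                                "weight": 1.0})
    iu = np.triu_indices(n_tfs, k=1)
    ppi_mask = rng.random(len(iu[0])) < ppi_density
    ppi_edges = pd.DataFrame({"source": [tfs[i] for i in iu[0][ppi_mask]],
                              "target": [tfs[j] for j in iu[1][ppi_mask]],
                              "weight": 1.0})
    return expr, motif_edges, ppi_edges, truth
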