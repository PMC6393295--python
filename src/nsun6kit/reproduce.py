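"""End-to-end reproduction harness.

Re-derives, at desk scale, the quantities the package models:

* panel truth tables - generated scaffolds for the characterized
  substrate panels and the mutant series, classified under both rule
  sets;
* kinetic constants - noiseless initial-rate data simulated from the
  reported Michaelis-Menten constants and re-estimated by the
  double-reciprocal procedure;
* melting midpoints - noiseless two-state melting curves simulated at
  the reported midpoints and re-estimated from the first derivative.

Everything is generated from the given seed; no external inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable

import pandas as pd

from .kinetics import fit_lineweaver_burk, simulate_initial_rates
from .recognition import builtin_panels, builtin_rulesets, classify_panel
from .reference import KINETIC_CONSTANTS, MELTING_POINTS_C
from .synth import generate_panel
from .thermal import MeltCurveModel, delta_tm, estimate_tm, simulate_melting_curve

__all__ = ["ReproductionRow", "ReproductionReport", "run_reproduce"]


@dataclass(frozen=True)
class ReproductionRow:
    target: str
    expected: float
    computed: float
    tolerance: float
    kind: str  # "count" | "absolute" | "relative"
    n: int

    @property
    def passed(self) -> bool:
        if self.kind == "relative":
            return abs(self.computed - self.expected) <= self.tolerance * abs(self.expected)
        return abs(self.computed - self.expected) <= self.tolerance


@dataclass(frozen=True)
class ReproductionReport:
    seed: int
    rows: tuple[ReproductionRow, ...]

    @property
    def n_passed(self) -> int:
        return sum(1 for r in self.rows if r.passed)

    @property
    def all_passed(self) -> bool:
        return self.n_passed == len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "target": r.target,
                    "expected": r.expected,
                    "computed": r.computed,
                    "tolerance": r.tolerance,
                    "kind": r.kind,
                    "n": r.n,
                    "passed": r.passed,
                }
                for r in self.rows
            ]
        )

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "n_targets": len(self.rows),
            "n_passed": self.n_passed,
            "rows": self.to_frame().to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2)

    def row(self, target: str) -> ReproductionRow:
        for r in self.rows:
            if r.target == target:
                return r
        raise KeyError(target)


def run_reproduce(seed: int = 0) -> ReproductionReport:
    """Run every reproduction target and collect the report."""
    rows: list[ReproductionRow] = []
    add = rows.append

    # -- panel truth tables -------------------------------------------------
    rulesets = builtin_rulesets()
    panels = builtin_panels()
    ph = rulesets["PhNSun6"]
    human = rulesets["hNSun6"]

    ph12 = generate_panel(panels["PH12"], base_seed=seed)
    hc3 = generate_panel(panels["HC3"], base_seed=seed)
    mutants = generate_panel(panels["MUTANTS"], base_seed=seed)

    ph12_vs_ph = classify_panel(panels["PH12"], ph, ph12.annotated)
    ph12_vs_h = classify_panel(panels["PH12"], human, ph12.annotated)
    hc3_vs_ph = classify_panel(panels["HC3"], ph, hc3.annotated)
    hc3_vs_h = classify_panel(panels["HC3"], human, hc3.annotated)
    mut_vs_ph = classify_panel(panels["MUTANTS"], ph, mutants.annotated)

    add(ReproductionRow("ph12_substrates_of_archaeal_enzyme", 11, ph12_vs_ph.n_substrates,
                        0, "count", len(ph12_vs_ph.members)))
    g73_ids = {m.id for m in panels["PH12"].members
               if m.constraints and m.constraints.get("n73") in {"G", "A"}}
    g73_hits = sum(
        1 for m in ph12_vs_ph.members
        if m.result.trna_id in g73_ids and m.result.substrate
    )
    add(ReproductionRow("g73_extension_panel_substrates", 7, g73_hits, 0, "count",
                        len(g73_ids)))
    eleven_hits = sum(
        1 for m in ph12_vs_h.members
        if m.result.trna_id != "PhtRNA-Phe(GAA)" and m.result.substrate
    )
    add(ReproductionRow("archaeal_substrates_accepted_by_human_enzyme", 0, eleven_hits,
                        0, "count", 11))
    add(ReproductionRow("human_substrates_accepted_by_archaeal_enzyme", 0,
                        hc3_vs_ph.n_substrates, 0, "count", 3))
    add(ReproductionRow("human_substrates_accepted_by_human_enzyme", 3,
                        hc3_vs_h.n_substrates, 0, "count", 3))

    def count_mutants(predicate: Callable[[str], bool]) -> tuple[int, int]:
        hits = total = 0
        for m in mut_vs_ph.members:
            if predicate(m.result.trna_id):
                total += 1
                hits += int(m.result.substrate)
        return hits, total

    c72_hits, c72_total = count_mutants(lambda i: "-C72" in i)
    add(ReproductionRow("c72_mutants_accepted", 0, c72_hits, 0, "count", c72_total))
    p271_hits, p271_total = count_mutants(lambda i: "C2G" in i)
    add(ReproductionRow("pair_2_71_swap_mutants_accepted", 0, p271_hits, 0, "count",
                        p271_total))
    rej_hits, rej_total = count_mutants(
        lambda i: i.endswith(("dCCA", "U73A", "U73C"))
    )
    add(ReproductionRow("cca_deletion_and_u73ac_accepted", 0, rej_hits, 0, "count",
                        rej_total))
    acc_hits, acc_total = count_mutants(
        lambda i: i.endswith("U73G") or "C3" in i or "C11" in i or "C12" in i
    )
    add(ReproductionRow("u73g_3_70_and_d_stem_mutants_accepted", 14, acc_hits, 0,
                        "count", acc_total))

    # -- kinetic recovery ---------------------------------------------------
    for label, key, expected_attr in (
        ("wildtype_thr_cgu", "Thr(CGU)", "both"),
        ("u73g_mutant", "Thr(CGU)-U73G", "both"),
        ("cys_gca", "Cys(GCA)", "kcat"),
    ):
        truth = KINETIC_CONSTANTS[key]
        data = simulate_initial_rates(truth, noise_sd_rel=0.0, seed=seed)
        fitted = fit_lineweaver_burk(data)
        n = len(data.substrate_concs)
        if expected_attr in ("both",):
            add(ReproductionRow(f"{label}_km_uM", truth.km, fitted.km, 1e-6,
                                "relative", n))
        add(ReproductionRow(f"{label}_kcat_per_min", truth.kcat, fitted.kcat, 1e-6,
                            "relative", n))

    # -- melting-midpoint recovery ------------------------------------------
    tm_unmod, tm_mod = MELTING_POINTS_C["Thr(CGU)"]
    curve = simulate_melting_curve(MeltCurveModel(tm_c=tm_unmod), noise_sd=0.0, seed=seed)
    est = estimate_tm(curve)
    add(ReproductionRow("thr_cgu_unmodified_tm_C", tm_unmod, round(est.tm_c, 1),
                        0.05, "absolute", len(curve.temperatures)))

    asp_unmod, asp_mod = MELTING_POINTS_C["Asp(GUC)"]
    est_unmod = estimate_tm(
        simulate_melting_curve(MeltCurveModel(tm_c=asp_unmod), noise_sd=0.0, seed=seed)
    )
    est_mod = estimate_tm(
        simulate_melting_curve(MeltCurveModel(tm_c=asp_mod), noise_sd=0.0, seed=seed)
    )
    add(ReproductionRow("asp_guc_delta_tm_C", asp_mod - asp_unmod,
                        delta_tm(est_mod, est_unmod), 0.1, "absolute",
                        len(curve.temperatures)))

    return ReproductionReport(seed=seed, rows=tuple(rows))
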