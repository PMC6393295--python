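# Methods

This note documents the models behind `nsun6kit`, the defaults and why
they were chosen, and what the package's synthetic data can and cannot
say about real tRNAs.

## Cloverleaf model and canonical numbering

A tRNA is modelled as the standard cloverleaf: 7-bp acceptor stem,
2-nt connector (positions 8–9), D-arm (3–4-bp stem, variable loop),
1-nt hinge (26), anticodon arm (5-bp stem, 7-nt loop with the
anticodon at 34–36), a variable region, T-arm (5-bp stem, 7-nt loop),
acceptor 3′ strand, discriminator (73) and the CCA terminus (74–76).
Canonical numbers follow the universal convention — acceptor pairs
1:72 … 7:66, D-stem pairs 10:25 … 13:22 — without insertion codes
(17a, e-positions); variable-region and D-loop residues carry no
canonical number. Base pairs are typed by sequence only: A:U/G:C (and
reverses) are Watson–Crick, G:U/U:G wobble, anything else a mismatch.

**Parsing** is template-based and 3′-anchored, not thermodynamic. If
the sequence ends in CCA the discriminator is the fourth residue from
the end; otherwise the last residue is taken as the discriminator and
`cca_present` is false (the CCA-deletion construct must remain
parseable). The acceptor 3′ strand is the seven residues 5′ of the
discriminator, paired against residues 1–7; at least 5 of the 7
positions must pair (WC or wobble), which tolerates the mismatch
introduced by C72 point mutants. The T-arm is the 17 residues
immediately preceding the acceptor 3′ strand. On the 5′ side the
D-stem is anchored at canonical position 10 and the D-loop length is
scanned (4–12 nt, stem size 4 then 3); the anticodon arm is placed
immediately after the 1-nt hinge. Among candidate geometries the
parser maximizes the number of paired stem positions and breaks ties
toward canonical geometry (4-bp D-stem, D-loop length nearest 8). The
anticodon stem must pair at ≥ 4 of 5 positions and the D-stem may have
at most one unpaired position; otherwise parsing fails with a
descriptive error. Anchoring plus canonical tie-breaks makes the parse
deterministic and immune to decoy stems that random loop residues
occasionally form — a fully paired canonical architecture always
achieves the unique maximal score.

One genuine ambiguity is surfaced rather than hidden: a CCA-less tRNA
whose residues 71–73 happen to spell C,C,A cannot be distinguished from
a CCA-terminated tRNA by sequence alone. The generator refuses that
constraint combination and `delete_cca` refuses to produce such a
molecule.

**Mutations** (`apply_point_mutation`, `apply_pair_swap`,
`delete_cca`) edit the raw sequence at the addressed canonical
position(s) and re-parse, so downstream annotations are always
consistent with the edited sequence.

**Extinction coefficients** at 260 nm are the base-composition sum of
monomer values (AMP 15 400, CMP 7 400, GMP 11 500, UMP 9 900
M⁻¹ cm⁻¹) with no hypochromicity correction — the simple additive
model, chosen for reproducibility; it overestimates the folded-RNA
coefficient by the usual ~10–20 %.

## Recognition rule sets

A `RuleSet` holds per-element constraints: CCA required or not, the
allowed residues at 72 and 73, allowed ordered pairs at 2:71 and 3:70,
and optional D-stem pair constraints. Pairs are ordered (5′, 3′)
tuples, so C2:G71 and G2:C71 are distinct — this single orientation
difference is what makes the two built-in rule sets mutually
exclusive.

* `PhNSun6` (archaeal): CCA, C72, N73 ∈ {U, G}, 2:71 = C:G; 3:70 and
  the D-stem unconstrained.
* `hNSun6` (human): CCA, C72, N73 = U, 2:71 = G:C. The human enzyme's
  additional D-stem and 3:70 preferences are representable in the
  `RuleSet` schema but deliberately left unconstrained: the built-in
  set encodes only what the characterized panels require, and every
  panel verdict is reproduced without them.

A tRNA is a substrate iff every constrained element matches; each
failure is reported with observed vs required values. Unparseable
sequences are classified as non-substrates with a parse-failure
violation rather than aborting batch runs. Verdicts are binary; the
quantitative differences between substrates (e.g. k꜀ₐₜ 4.30 vs 3.04
min⁻¹) belong to the kinetics module, not the classifier.

Two judgement calls in the built-in panels: the seven G73 substrates
are encoded with C2:G71 (stated collectively, not printed per tRNA for
all members), and G2:U71-bearing tRNAs — present in the genome but
never assayed — are rejected by the archaeal rule set, an extrapolation
from the C2:G71 requirement.

## Synthetic scaffolds

Real *P. horikoshii* tRNA sequences are not bundled; scaffolds are
generated to order. Geometry is fixed: 76 nt with a 5-nt variable
region, or 85 nt with a 14-nt unstructured variable arm for type-II
(serine) scaffolds; 8-nt D-loop; U8/A9 connector; U33 and A37 flanking
the anticodon; T-loop with the U54-U55-C56/A58 consensus. Constrained
positions (N72 via its 1:72 partner, N73, pairs 2:71, 3:70, 11:24,
12:23, CCA) are set exactly; the remaining 16 stem pairs are
Watson–Crick draws whose G:C probability is tuned so the expected
overall GC content meets the target (default 0.7, emulating
hyperthermophile tRNAs; loops are uniform draws). The tuning is
computed against a fixed reference composition so that changing one
element constraint never perturbs the pseudo-random draw stream —
regenerating with one changed constraint changes only the positions
that constraint implies. Every scaffold is verified to round-trip
through the parser with exactly the requested element profile before
it is returned.

Panel mutants are produced by applying the named mutation operations to
one shared wild-type scaffold, never by independent sampling, so each
mutant differs from the reference only at the mutated positions —
mirroring how the mutant transcripts were constructed.

What passing tests show: the rule sets, the classifier, and the parser
agree on sequences with canonical geometry and the stated identity
elements. What they do not show: behaviour on natural sequences with
non-canonical D-loop sizes, modified nucleosides, or intron-containing
pre-tRNAs; the generator's loop sequences are random, not phylogenetic.

## Steady-state kinetics

Initial velocities follow v = k꜀ₐₜ·[E]·[S]/(Kₘ+[S]), with enzyme
entered in nM and converted to µM internally. The default assay design
mirrors the methylation experiments: [E] = 100 nM, eight substrate
concentrations spanning 0.1–40 µM (0.1, 0.25, 0.5, 1, 2.5, 5, 10,
40), time points 2–8 min. Noise is multiplicative Gaussian with a
relative SD (scintillation-type errors scale with signal), redrawn per
point to keep rates positive; it is mean-preserving to within Monte
Carlo error.

Parameter estimation is deliberately the classical double-reciprocal
procedure: unweighted OLS of 1/v on 1/[S], Vmax = 1/intercept,
Kₘ = slope/intercept, k꜀ₐₜ = Vmax/[E]. Its bias under noise is well
known (the smallest rates dominate the reciprocal fit); it is retained
because it is the stated estimation procedure for the benchmark
constants, and on noiseless data it is exact. A direct nonlinear
least-squares fit ships alongside purely as a cross-check; tests
assert the two agree exactly on noiseless data, and that under 5 %
noise the median double-reciprocal estimates stay within 10 % of
truth at the standard design. Initial rates can also be taken as the
least-squares slope of a simulated progress curve over an early time
window; this matches the closed-form rate to < 2 % while substrate
consumption stays below 10 %.

Co-substrate (SAM) dependence, product inhibition and thermal
inactivation are out of scope; assay temperature is metadata only.

## Thermal stability

Melting curves follow a two-state van't Hoff model with
temperature-independent enthalpy: θ(T) = 1/(1 + exp((ΔH_vH/R)(1/T −
1/T_m))) in kelvin, absorbance A(T) = (1−θ)·folded(T) + θ·unfolded(T)
with linear baselines, plus optional additive Gaussian noise. Defaults:
ΔH_vH = 250 kJ/mol (a mid-range value for tRNA tertiary unfolding,
giving a ~13 °C transition), flat baselines 0.25 → 0.30 AU (initial
A₂₆₀ held at 0.2–0.3 in the assay), scan 25–95 °C. The instrument scans
at 1 °C/min; simulation defaults to a 0.1 °C grid for estimator
accuracy, and the 1 °C instrument cadence is exercised in tests.

Tm is read from the first derivative of the melting curve: centred
moving-average smoothing (default 5 points), central differences, and
a least-squares parabola through the peak neighbourhood. Two numerical
choices matter:

* **Derivative axis.** For the van't Hoff sigmoid the maximum of dA/dT
  lies measurably below the thermodynamic midpoint (≈ 0.17 °C at
  250 kJ/mol), because θ′(T) carries a 1/T² factor. The estimator
  therefore locates the peak of −dA/d(1/T) = T²·dA/dT, which for flat
  baselines peaks exactly at θ = ½, i.e. at T_m; the plain dA/dT
  variant remains available via `method="dA/dT"` and the choice is
  recorded in the estimate. Reported peak heights are always quoted on
  the temperature axis (AU/°C).
* **Peak refinement bandwidth.** The parabola is fitted over
  ± half the smoothing window, so the refinement widens with the
  smoothing chosen for noisy data. On noiseless curves the default
  window recovers generating midpoints to < 0.001 °C (and within half
  a grid step for off-grid midpoints). For noisy instrument data the
  window should be matched to, but kept below, the transition width
  ΔT ≈ 4RT_m²/ΔH_vH (≈ 13 °C here): with 0.002 AU noise on a 0.05 AU
  transition, a 10.1 °C window yields a median absolute Tm error of
  ≈ 0.18 °C over 200 replicates, against a Cramér–Rao floor of
  ≈ 0.06 °C.

ΔTm is reported as modified − unmodified, rounded to 0.1 °C to match
the precision of the benchmark table; internal values keep full
precision. A derivative maximum at a scan boundary raises an error
(truncated transition) instead of returning a boundary value. Fitting
ΔH_vH from data, three-state unfolding, ionic-strength dependence and
hysteresis are out of scope: Tm is the only readout modelled.

## Reproduction harness and problem sizes

`nsun6kit.reproduce.run_reproduce` (and `scripts/acceptance.py`)
regenerate every benchmark quantity from scratch at desk scale: panels
of 3–22 scaffolds of 73–85 nt; kinetic fits on 8-point noiseless
datasets (noise studies use 200–500 replicates); melting curves of 701
points. A full run completes in seconds. Deterministic quantities are
seed-invariant by construction; stochastic studies derive all
randomness from the run seed.

## Known limitations

* The parser assumes canonical arm order and sizes; organellar,
  truncated or intron-containing tRNAs are out of scope.
* The classifier is binary and sequence-level; it does not predict
  methylation rates or model the N73 binding pocket structurally.
* GC-content targeting is exact only in expectation and saturates near
  the extremes of the allowed [0.4, 0.9] range once all free stem
  pairs are G:C or A:U.
* The double-reciprocal estimator is biased under noise by design
  fidelity; use the nonlinear fit for real noisy data.
* Melting noise is additive white Gaussian; real melts show drift,
  smooth baselines curvature and occasional aggregation signatures
  that the two-state model does not capture.
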