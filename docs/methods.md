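# Methods

## The problem

Anatomical angiographic scores grade the extent and complexity of coronary
artery disease from a coronary angiogram, for risk stratification and for
choosing between percutaneous intervention and bypass surgery. The classical
SYNTAX score assigns each coronary segment a fixed, nomenclature-based
weighting factor that depends only on a binary right/left dominance label,
multiplies it by 5.0 for a total occlusion or 2.0 for a 50–99% stenosis, and
adds directly assigned points for adverse lesion characteristics
(bifurcation, calcification, thrombus, ...).

That construction has known structural weaknesses, all of which this package
makes computable:

1. **Dominance dichotomy.** RCA supply to the left ventricle is a continuum;
   a binary dominance label collapses it.
2. **Flow-conservation violation.** Along the RCA the parent segments are
   weighted 1.0 while their daughters (PDA at 1.0 plus posterolateral
   branches at 0.5 each) sum well above 1.0. A parent vessel's blood flow —
   hence its weight — should equal the sum of its daughters'.
3. **Mixed components.** Lesion-severity points and arbitrarily assigned
   adverse-characteristic points are summed into one number.
4. **Missing modification.** A side branch arising proximal to a lesion means
   direct scoring overestimates the jeopardised territory.

The CatLet (Coronary Artery Tree description and Lesion EvaluaTion) score
addresses these by weighting each vessel by **how many of the 17 LV segments
it supplies** (1 segment = 1 mass unit ≈ 1 flow unit), classifying the
circulation pattern into 6 RCA × 3 LAD × 3 diagonal = **54 types**, recording
the eight adverse characteristics **qualitatively only**, and supporting an
adapted side-branch modification.

## Model and procedure

**Data model** (`coronary_model`). An angiogram description is a forest of at
most three rooted vessel trees; terminal nodes carry supplied-segment counts
that must sum to exactly 17; lesions attach to one node each (a multi-segment
lesion is entered as several lesions). Counts and weights are exact
`fractions.Fraction`s so every conservation check is bit-exact; output is
formatted to one decimal ("7.0", "3.5"). A lesion is scored only at ≥50%
diameter stenosis (inclusive) on a vessel >1.5 mm (strict), exactly as the
criteria are punctuated.

**Weights** (`pattern_weights`). A pattern maps through an allocation table
to per-vessel supplied-segment counts. The LCX is never tabulated: by the law
of competitive blood supply its territory is the residual,
LCX = 17 − (LAD + Dx + PDA + PLV). Terminal weight = its count; internal
weight = sum of daughters (law of flow conservation), so root weights always
sum to 17.

The canonical per-type allocation matrix is published separately and not
available here; the shipped default is an explicit **non-canonical stand-in**
built from the stated laws, monotone along each axis:

| axis | categories | counts |
|---|---|---|
| RCA (PDA, PLV) | PDA zero → super RCA | (0,0), (1,0), (2,1), (2,2), (3,2), (3,3) |
| LAD | short / average / long | 6 / 7 / 8 |
| Dx | small / intermediate / large | 1 / 2 / 3 |

"PDA only" is read as PLV = 0 exactly. LAD "average" = 7 reproduces the
worked weighting example (LAD supplying 7 segments → factor 7.0). The maximal
combination 8 + 3 + 6 = 17 leaves LCX ≥ 0 everywhere. The table is exported
and replaced via CSV (`catlet allocation-table`, `--allocation-table`).

**CatLet scoring** (`catlet_engine`). Per eligible lesion:
value = w · m − subtrahend, floored at 0, with m = 5.0 for any total
occlusion (acute or chronic, native or in-stent) and 2.0 otherwise; lesions
carry one of six type labels (native/in-stent × nonocclusion/ATO/CTO). The
adapted modification subtracts each preceding side branch's weight scaled by
the lesion's own m (the worked case: 3.5×5 − 1.0×5 = 12.5); it is switchable
and the branch list is recorded on the lesion, because the tree graph does
not encode intra-segment position. Adverse flags are recorded verbatim for
every lesion and contribute nothing numerically; diffuse disease / small
vessels is excluded from every quantitative path. Totals bin at the tertiles
≤9 / 10–14 / >15. The printed bands leave (14, 15] unassigned; such totals
are binned intermediate and flagged in the report (`tier_note`).

**SYNTAX scoring** (`syntax_engine`). The right-dominance RCA rows (segments
1–4 at 1.0; 16/16a/16b/16c at 0.5) are fixed; all other right-dominance
segments are completed from the published SYNTAX/Leaman convention and every
entry carries a provenance tag (`rca_table` / `standard` / `user`).
Left-dominance rows are config-only. Adverse-characteristic points have no
published evidence base; they live in an editable config with SYNTAX-style
defaults, the engine refuses to score flagged lesions without a config
(no silent zeros) unless `lesion_only` is requested, and the lesion and
adverse components are always reported separately. `flow_conservation_audit`
compares w(parent) with Σ w(daughters) at every internal node: on the
tabulated weights it flags the distal RCA (1.0 vs 3.0 with four
posterolateral rows; the three sub-branches 16a–16c alone sum to 1.5 — the
discrepancy between the 1.5 figure and the four tabulated 0.5 rows is
surfaced, not resolved); on derived CatLet weights it finds nothing, by
construction. SYNTAX tertiles: <23 / 23–33 (low boundary inclusive) / ≥33.

**Statistics** (`agreement_stats`). Weighted Cohen's kappa
κ = 1 − D_o/D_e with disagreement weights none/linear/quadratic (default
linear — the weighting scheme behind published reproducibility figures is
rarely stated, so every result carries its scheme name). Labels: slight
0.0∼0.2, fair 0.2∼0.4, moderate 0.4∼0.6, substantial 0.6∼0.8, almost perfect
0.8∼1.0, with shared boundaries assigned to the upper band and κ<0 labelled
"poor (below chance)". The degenerate case p_e = 1 (both raters constant and
identical) is defined as κ = 1 with a warning. Optional seeded bootstrap
percentile CI. Category-free NRI = [P(up|event) − P(down|event)] +
[P(down|nonevent) − P(up|nonevent)] with ties as no movement (tie policy for
published headline values is unknown and not guessed); z uses the standard
large-sample variance of the two net proportions, p two-sided normal.
Tier reclassification tables count outcome-concordant moves (up for events,
down for nonevents) as percentages of each group.

## Synthetic data

`synth_cohort` generates structure, not clinical epidemiology, and all
generators are pure functions of a `GeneratorSpec` (PCG64, fixed seed;
identical spec ⇒ bit-identical output):

- **Trees**: pattern uniform over the 54 types on a fixed 12-node forest
  skeleton; lesion count Poisson (default rate 2.0/tree); non-occlusive
  stenosis uniform on [50, 99]%; occlusions (probability 0.25) at 100% split
  evenly acute/chronic; adverse flags independent Bernoulli(0.15); reference
  diameters uniform on [2.0, 4.0] mm so generated lesions are eligible.
- **Rating pairs**: rater A uniform over k categories; B flips each item to a
  different category with the disagreement rate. For this model the linear
  weighted kappa has a closed form used as a recovery oracle in tests
  (≈ 1 − 1.5r at k = 3).
- **Outcome cohorts**: old scores uniform on [0, 40]; event probabilities
  monotone in CatLet tier (0.05/0.15/0.30); new = old + N(0, 1) +
  strength·(±1 by outcome). Strength 0 is the NRI null; large strength gives
  deterministic separation (NRI → 2).

What passing tests therefore show: the arithmetic, conservation laws,
filtering rules and statistics are implemented exactly. What they do not
show: anything about real lesion distributions, real observer behaviour, or
clinical outcome prediction — reproducing published cohort statistics (NRI
37.2%, the kappa series) requires patient data and is out of scope.

## Numerical choices and problem sizes

- Exact rational arithmetic for all scores and weights; floats only at the
  statistics layer and on output.
- Oversubtracting modifications clamp at 0 with a recorded warning.
- Tier functions partition [0, ∞); negative scores are domain errors.
- Test problem sizes: 10,000-tree conservation sweep, 2,000-tree pattern
  coverage (coupon-collector), n = 5,000 NRI null (|NRI| < 0.05), n = 2,000
  kappa recovery (±0.05); the whole suite runs in well under a minute.

## Known limitations

- The shipped allocation table and SYNTAX adverse points are labelled
  stand-ins/defaults; users with the canonical tables should load them.
- Culprit-vessel indication is annotation only.
- One lesion, one node; no intra-segment geometry beyond the recorded
  preceding-branch list.
- No image processing, no physiology (FFR), no clinical covariate models.
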