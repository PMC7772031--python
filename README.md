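# catlet

CatLet and SYNTAX coronary angiographic scoring over a shared coronary-tree
data model, with the agreement and reclassification statistics used to
validate angiographic scores.

**Who it is for.** Interventional cardiology researchers and core-lab
engineers who need reproducible, auditable implementations of two anatomical
CAD-complexity scores — the classical SYNTAX lesion score and the CatLet
(Coronary Artery Tree description and Lesion EvaluaTion) score — plus the
statistics (weighted Cohen's kappa, category-free net reclassification
improvement) used to compare them.

**The scores.** Both score an eligible lesion (≥50% diameter stenosis on a
vessel >1.5 mm) as *weight × factor*, with factor 5.0 for a total occlusion
and 2.0 otherwise. They differ in the weight:

- **SYNTAX** uses fixed nomenclature-based segment weights under a binary
  dominance label (e.g. proximal LAD 3.5, PDA 1.0, each posterolateral
  branch 0.5) and adds directly assigned points for adverse lesion
  characteristics. These weights violate the law of flow conservation —
  along the RCA, parents weigh 1.0 while their daughters sum to 3.0 — which
  the package's `flow_conservation_audit` demonstrates.
- **CatLet** weights a vessel by how many of the 17 LV segments (1 segment =
  1 mass unit) it supplies, under one of 54 circulation-pattern types
  (6 RCA × 3 LAD × 3 diagonal); an LAD supplying 7 segments weighs 7.0.
  Internal weights are sums of daughters, so conservation holds exactly, and
  the eight adverse characteristics are recorded qualitatively, never scored.

Both engines support the adapted modification for a side branch preceding
the lesion: an occluded proximal LAD with a significant diagonal scores
3.5 × 5 = 17.5 directly, reasonably modified to 3.5 × 5 − 1.0 × 5 = 12.5.
Risk tiers: SYNTAX <23 / 23–33 / ≥33; CatLet ≤9 / 10–14 / >15.

See `docs/methods.md` for the full model, the shipped (stand-in) allocation
table, and numerical conventions.

## Worked example

```python
from catlet import (
    read_angiogram, figure2_fixture_path, derive_vessel_weights,
    catlet_total, syntax_total,
)

tree = read_angiogram(figure2_fixture_path())   # occluded proximal LAD,
                                                # significant diagonal before it
print(float(syntax_total(tree, modification=False, lesion_only=True).total))
# 17.5   <- direct SYNTAX scoring: 3.5 x 5
print(float(syntax_total(tree, modification=True, lesion_only=True).total))
# 12.5   <- adapted modification: 3.5 x 5 - 1.0 x 5

weights = derive_vessel_weights(tree)           # segment-supply weights
report = catlet_total(tree, weights)
print(float(report.total), report.tier)
# 35.0 high   <- CatLet: the occluded proximal LAD jeopardises 9 mass units
#               (7 LAD + 2 diagonal); 9 x 5 minus the diagonal's 2 x 5
```

The same case from the shell:

```sh
catlet syntax $(python -c "import catlet; print(catlet.figure2_fixture_path())") --modification
catlet score  $(python -c "import catlet; print(catlet.figure2_fixture_path())")
catlet synth trees --n 100 --seed 42 --out cohort/   # synthetic angiograms + scores.csv
```

Statistics:

```python
from catlet import weighted_kappa, category_free_nri
r = weighted_kappa([0,1,2,1,0,2], [0,1,1,1,0,2])   # linear weights by default
print(round(r.kappa, 3), r.label)
# 0.8 almost perfect
```

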