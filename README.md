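# ismkit

Interpretive structural modeling (ISM) with MICMAC classification, for
turning expert pairwise judgments about directed influence among factors
into a leveled hierarchical model.

ISM is the standard tool in health-policy and management research for
making sense of a small system of interdependent factors when no
statistical data exist: a panel of experts ratifies a factor list, judges
every factor pair, and the method derives which factors drive the system
and which are driven. `ismkit` implements the complete classical chain and
ships, as a worked case study, the full elicitation record of a published
desk-scale study of the determinants of COVID-19 SOP effectiveness in mass
gatherings (11 factors, 10 experts).

## The method

For factors 1..n, each expert fills the strict upper triangle of a
**structural self-interaction matrix (SSIM)** with one symbol per pair
(i, j): `V` (i leads to j), `A` (j leads to i), `X` (both), `O` (neither).
Panel judgments are aggregated per pair by majority. The SSIM decodes into
the binary **initial reachability matrix** M (diagonal 1), which is made
transitive — either to a fixed point (Warshall closure, cells added as
`1*`) or by the single pass M ∨ M·M many desk studies apply by hand.

From the final matrix R:

- **driving power** d(i) = Σ_j R(i,j), **dependence power** e(j) = Σ_i R(i,j);
- **level partitioning**: iteratively, factor i is assigned to the current
  (top) level when its reachability set equals reachability ∩ antecedent
  within the remaining factors; Level I is the top of the model, the
  deepest level its most critical drivers;
- the **conical matrix** permutes R into level order; the **digraph**
  condenses strongly connected components and transitively reduces the
  result, one rank per level;
- **MICMAC** plots each factor at (e, d) and splits the plane at n/2:
  *independent* (d high, e low), *dependent* (d low, e high), *linkage*
  (both high), *autonomous* (both low); the net influence d − e
  ("effectiveness") summarizes each factor's push on the system.

## Worked example

```python
from ismkit import (load_case_study, compute_powers, partition_levels,
                    classify_factors, summarize, MicmacConfig)

study = load_case_study()           # 11 factors, 10-expert panel
powers = compute_powers(study.final_rm)
levels = partition_levels(study.final_rm)
micmac = classify_factors(powers, MicmacConfig(n=11))
print(levels.as_dict())
print(summarize(study.roster, levels, micmac).head(3).to_string(index=False))
```

prints

```
{'I': (6, 7, 8, 10), 'II': (2, 5, 9, 11), 'III': (3, 4), 'IV': (1,)}
code                                       label  driving  dependence  effectiveness     cluster level    comment
   1                         Nature of gathering       11           2              9 Independent    IV Key factor
   2                 Type of gathering community        9          10             -1     Linkage    II
   3 Available physical space at gathering place       10           8              2     Linkage   III
```

— a four-level model whose bottom factor ("nature of gathering", driving
power 11, dependence 2) is the key driver of SOP effectiveness, while
"perceived benefit of adapting SOPs" (driving 4, dependence 11) is purely
dependent and the remaining nine factors are unstable linkage factors.

The same run from the shell, with all intermediate artifacts written to
`out/` (SSIM, matrices, iteration tables, conical matrix, DOT digraph,
markdown report):

```bash
ismkit run --case-study --out out
```

The published final matrix is used *as given*: the closure audit
(`ismkit audit`) reports that it differs from the recomputed one-pass
closure at exactly one cell, (7,1), and that the full Warshall closure
would collapse the model to two levels — documented discrepancies of the
source data that the toolkit reports rather than silently repairs.

A seeded synthetic generator (`ismkit simulate`, `ismkit.synthetic`)
produces ground-truthed hierarchies and noisy expert panels in the same
CSV formats, so every pipeline stage can be exercised and its recovery
behavior measured without field data.

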