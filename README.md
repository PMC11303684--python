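# chitosim

Simulation and statistics of chitosan acetylation patterns.

Chitosans are linear copolymers of N-acetyl-D-glucosamine (**A**-units) and
D-glucosamine (**D**-units). Three structural parameters govern their
physicochemical behavior and bioactivity: the degree of polymerization
(DP), the fraction of acetylation (F_A), and the *pattern* of acetylation
(PA) — how the A-units are arranged along the chain. The PA is the hardest
to measure; one productive strategy is enzymatic/chemical fingerprinting:
depolymerize the chitosan with an agent of known subsite specificity and
read the pattern off the product length distribution.

`chitosim` is a toolkit for the in silico side of that strategy, for
glycoscientists and method developers. It provides:

* **Chain generators** — populations of chains under position-dependent
  Bernoulli acetylation, with a tunable overrepresentation of A-units at
  every third position ("pattern strength" *s* ∈ [0, 1], from fully random
  to the ideal (DDA)ₙ repeat), plus a capped time-course mode emulating
  heterogeneous deacetylation with protected pattern units.
* **A cleavage engine** — complete or partial digestion at sites defined by
  subsite requirements at positions −2, −1, +1, +2 around the scissile
  bond (e.g. `DA|XX` for the chitinosanase AaChio, `XD|XX` with
  deamination for nitrous acid; presets for AaChio, CsnMN, GH18, GH19,
  TFA, HNO2).
* **Pattern statistics** — product DP distributions (molar or
  mass-weighted), the **triad strength**

      triad strength = (c₃ + c₆) / (c₂ + c₄ + c₅)

  over DP 2–6 product amounts (values > 1 flag DP = 3n overrepresentation),
  composition profiles, number-average A-/D-block sizes, diad/triad
  frequencies, and the diad-based **PA value**

      PA = (F_AD + F_DA) / (2 · F_A · F_D)

  scaled so 0 = perfectly block-wise, 1 = perfectly random,
  2 = perfectly alternating. A closed-form fragment-length law for DA|XX
  digestion of random chains serves as an analytic cross-check of the
  simulator.
* **Experiment drivers + CLI** — seeded end-to-end pipelines (DP profiles
  across pattern strengths, triad-strength landscapes over F_A × s,
  partial-deamination step analysis, capped deacetylation time courses),
  all emitting long-format TSV tables.

## Worked example

Generate 500 chains of DP 1000 at F_A = 0.32 with pattern strength 0.5,
digest them completely with the AaChio specificity, and analyze:

```sh
chitosim generate --n 500 --dp 1000 --fa 0.32 --s 0.5 --seed 7 --out pop.fasta
chitosim cleave --in pop.fasta --spec AaChio --out frags.tsv
chitosim analyze --in frags.tsv --metrics triad-strength,block-sizes
chitosim analyze --in pop.fasta --metrics pa-value,fa
```

prints (fragment metrics, then population metrics):

```json
{
  "triad_strength": 1.575424291267659,
  "mean_a_block": 1.3109593304178337,
  "mean_d_block": 2.7838435457717066
}
{
  "fa_observed": 0.320152,
  "pa_value": 1.1196068413084914
}
```

The triad strength of 1.58 (> 1) flags the overrepresentation of DP = 3n
products caused by the every-third-position bias — a random-PA substrate of
the same F_A gives ≈ 0.6. The PA value of 1.12 sits barely above the
random anchor of 1.0, illustrating why diad-based (NMR-type) analysis is
nearly blind to this pattern even though the digest fingerprint detects it
clearly. The block sizes say the average uninterrupted A-run is 1.31 units
and the average D-run 2.78 units.

The same pipelines are available from Python:

```python
from chitosim import (GeneratorParams, PRESETS, generate_patterned,
                      digest_population, dp_distribution, triad_strength)

pop = generate_patterned(GeneratorParams(500, 1000, fa=0.32, s=0.5, seed=7))
frags = digest_population(pop, PRESETS["AaChio"])
print(triad_strength(dp_distribution(frags)))
```

## Documentation

`docs/methods.md` describes the generative model, the cleavage rules, the
statistics and their estimators, the numerical choices, and what the
synthetic populations do and do not capture about real chitosans.
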