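# paleowean

Bayesian reconstruction of breastfeeding and weaning practice from
bone-collagen stable isotopes in archaeological skeletal series.

Breastfeeding infants sit one trophic level above their mothers, so their
bone-collagen δ15N is elevated by ~2–4 ‰ until weaning foods replace breast
milk; δ13C separates C₃-plant weaning foods from marine/C₄-influenced adult
diets.  Two obstacles make naive readings of juvenile collagen unreliable:
bone collagen integrates diet over a turnover window that shrinks dramatically
with age, and source contributions depend on elemental concentrations and
diet→collagen fractionation, not just isotope ratios.  `paleowean` implements
a complete pipeline that addresses both, built around a Caribbean
fisher-horticulturalist skeletal series (31 juveniles, 18 adult females)
bundled as plain-text fixtures:

1. **Collagen QC and age grouping** — preservation screen (%N ≥ 4.8,
   %C ≥ 13, atomic C/N in [2.9, 3.6]), parsing of printed age estimates, and
   binning into four age groups (0–0.5, 0.5–1, 1–2, 2–6 y).
2. **Breast-milk source inference** — the unmeasurable milk source is derived
   from adult-female collagen through literature tissue-offset chains
   (milk↔keratin↔collagen), with Δ(a→b) = δ_b − δ_a conventions.
3. **Concentration-dependent Bayesian mixing model** — for consumers *i*,
   isotopes *j*, sources *k* with proportions **p** on the simplex:

   ```
   x_ij ~ Normal( m_j(p), v_j(p, σ) )
   m_j  = Σ_k p_k q_jk (μ_jk + Δ_jk) / Σ_k p_k q_jk
   v_j  = Σ_k w_jk² (s_jk² + s_Δjk²) + σ_j²,   w_jk = p_k q_jk / Σ p q
   p ~ Dirichlet(1),  σ_j ~ half-Normal(5 ‰)
   ```

   sampled by random-walk Metropolis on an additive-log-ratio
   reparameterisation, with split-chain R-hat diagnostics.  Posterior
   proportions are summarised by boundary-reflected KDE modes and 2.5/97.5
   percentile intervals.
4. **Weaning-age reconstruction by ABC** — juvenile δ15N follows a two-phase
   diet trajectory (breastfeeding plateau, linear decline between the start
   t₁ and end t₂ of weaning, weaning-food plateau) filtered through
   age-dependent collagen turnover:

   ```
   dδcol/dt = r(t) (δdiet(t) − δcol(t)),   r(t) = r∞ + (r₀ − r∞) e^(−t/τ)
   ```

   inverted by rejection ABC (uniform priors, RMS distance, kernel-density
   maximum-density estimates).
5. **Group statistics** — Shapiro–Wilk, one-way ANOVA, Tukey–Kramer pairwise
   comparisons with unequal group sizes.
6. **Synthetic cohorts** — generators for females, juvenile weaning
   trajectories and mixture consumers with known ground truth, used by the
   parameter-recovery and calibration tests.

## Worked example

```python
import paleowean as pw
from paleowean.mixing_model import MixingConfig, fit_mixing
from paleowean.warn_model import ABCConfig, TurnoverModel, fit_warn_abc

samples = pw.load_samples(pw.bundled_samples_path())
groups = pw.group_juveniles(samples)
females = pw.summarize_group(groups["females"], "females")
print(f"adult females: n={females.n}, d15N = {females.mean_d15N:.2f} "
      f"+/- {females.sd_d15N:.2f} permil")

milk = pw.milk_source_from_females(females)
print(f"inferred breast milk: d15N = {milk.mu_N:.2f}, d13C = {milk.mu_C:.2f} permil")

sources = [milk] + [s for s in pw.load_bundled_sources() if s.name != "Breast Milk"]
post = fit_mixing(groups["G3"], sources,
                  MixingConfig(n_iterations=20_000, n_burn=10_000, thin=5, rng_seed=1),
                  group_label="G3")
for name, mode, lo, hi in zip(post.source_names, post.mode_pct, post.lci_pct, post.hci_pct):
    print(f"  {name:15s} mode {mode:3.0f}%   95% CI [{lo:.0f}, {hi:.0f}]")

juv = [(s.age.midpoint, s.d15N) for g in ("G1", "G2", "G3", "G4") for s in groups[g]]
w = fit_warn_abc(juv, females.mean_d15N, TurnoverModel(),
                 ABCConfig(n_sims=300_000, accept_fraction=0.005, rng_seed=1))
print(f"weaning: t1 MDE {w.mde.t1:.2f} y, t2 MDE {w.mde.t2:.2f} y")
print(f"enrichment MDE {w.mde.enrich:.2f} permil, "
      f"weaning-food collagen MDE {w.mde.d15N_wnfood:.2f} permil")
```

prints

```
adult females: n=18, d15N = 10.91 +/- 1.19 permil
inferred breast milk: d15N = 7.39, d13C = -19.55 permil
  Breast Milk     mode  76%   95% CI [4, 93]
  Root Cultigens  mode   0%   95% CI [0, 62]
  Legumes         mode   0%   95% CI [0, 36]
  Tropical Fruits mode   0%   95% CI [1, 72]
weaning: t1 MDE 2.52 y, t2 MDE 2.85 y
enrichment MDE 0.83 permil, weaning-food collagen MDE 6.59 permil
```

Reading: the female collagen mean (10.91 ‰) minus the maternal
milk→collagen offset gives a breast-milk source at 7.39 ‰; for the 1–2-year
group, breast milk is the dominant protein source (posterior mode 76 %,
though with a wide credibility interval typical of a four-source mixture fit
to eight consumers); the weaning trajectory inverted against all 31 juveniles
puts the end of weaning just before age three, with weaning foods whose
collagen-equivalent δ15N (≈ 6.6–7 ‰) sits well below the breastfeeding
plateau — depleted C₃ plants such as root cultigens.

A command-line interface mirrors the library:
`paleowean run|qc|mix|wean|stats|simulate` (see `paleowean --help`).

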