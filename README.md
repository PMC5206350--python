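# phytomer

Simulation and reconstruction of phytomer elongation kinetics in a
vegetative C4 grass (*Cleistogenes squarrosa*-type tillers).

A grass tiller is a stack of **phytomers** — repeating units of leaf
blade, leaf sheath, node and internode. A young phytomer elongates
hidden inside the sheath tube of older phytomers; only after its blade
tip grows past the highest visible ligule can a ruler measure it. This
package addresses the resulting reconstruction problem faced by anyone
quantifying grass development from daily ruler readings and one
destructive harvest:

* infer **tip-emergence times** (lag-corrected for daily sampling) and the
  **phyllochron** (days between successive emergences),
* extrapolate **final lengths** of still-growing phytomers from the
  per-tiller mature length-vs-rank line,
* normalize lengths to the **fraction of final length**, `f_L = L_a / L_p`,
* date unemerged phytomers by anchoring one immature phytomer (60–80 % of
  final length) on the fitted visible curve and stepping down whole
  phyllochrons,
* fit the **complete developmental time course**
  `f_L(x) = 1 / (1 + exp((x0 − x)/b))`, with `x` in days after tip
  emergence, alongside the within-phytomer (blade/sheath/internode) and
  between-phytomer coordination curves.

Because the original greenhouse data are not deposited, the package
includes a first-class forward simulator: tillers grown under the
empirical coordination rules (logistic time course with midpoint
`x0 = 1.82 d` and scale `b = 1.81 d`; blade→sheath→internode partition at
50/75/80 % of final length; ~20 % decline in final length from rank 8 to
13; 2×2 nitrogen × vapour-pressure-deficit design with 16 tillers per
treatment), observed through an explicit 1-D height model with 0.5 mm
rounding, daily sampling on days 24–37 and a >4 mm dissection rule. Every
reconstruction stage can therefore be validated against known truth.

## Worked example

```python
from phytomer import synthetic_data as sd, reconstruct
from phytomer import summaries as sm

cfg = sd.default_config(seed=0)            # 4 treatments x 2 chambers x 8 tillers
obs, diss, truth = sd.generate_experiment(cfg)
recon = reconstruct(obs, diss)

fit = recon.complete_fit
print(f"x0={fit.curve.midpoint:.2f} d  b={fit.curve.scale:.2f} d  "
      f"R2={fit.r_squared:.3f}  n={fit.n_points}")

summ = sm.summarize_tillers(recon, obs, truth)
table = sm.treatment_means(summ)
print(f"phyllochron grand mean: {sm.grand_mean(table, 'phyllochron'):.2f} d")
```

prints

```
x0=1.67 d  b=1.80 d  R2=0.994  n=719
phyllochron grand mean: 2.32 d
```

The recovered sigmoid midpoint (1.67 d) and scale (1.80 d) sit within
10 % of the generating values (1.82, 1.81): the time of maximal growth
rate lands about 2 days after tip emergence, and the 2.32 d phyllochron
reproduces the configured treatment cells (2.4 / 2.4 / 2.1 / 2.4 d,
recovered as 2.40 / 2.39 / 2.02 / 2.46 d). The small downward shift of
`x0` is the documented footprint of the estimation chain itself
(emergence-lag correction at daily sampling, normalization by a final
length reached at 99 % of the asymptote); see `docs/methods.md`.

The same pipeline runs from the shell:

```sh
phytomer full --seed 0 --out run/     # simulate + analyze + summarize
phytomer simulate --seed 7 --out data/
phytomer analyze --observations data/observations.csv --dissection data/dissection.csv
```

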