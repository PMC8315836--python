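# crowdwise

Simulation and statistical analysis of **social influence in group
estimation tasks** — the "wisdom of crowds" setting in which members of a
group first estimate a quantity independently, then see some of their
peers' estimates and estimate again.

The package is aimed at researchers in collective behaviour and social
decision-making who want to (i) simulate balanced estimation experiments
under different *social-information display* regimes, and (ii) fit the
behavioural quantities such experiments are analysed with, on either
simulated or externally supplied tabular data.

## The setting and the model

Estimates are analysed in log space normalised by the truth,
`X = log10(E / T)`: the deviation from the truth in orders of magnitude.
Per question, personal estimates `X_p` follow a Laplace distribution of
centre `c` and width `w`, truncated below at `-log10(T)` (raw estimates
cannot fall below 1). The default question generator gives `c` a negative
mean — the well-documented tendency of crowds to underestimate.

Each subject receives the estimates of `τ` random peers (never their
own), shown either **sorted** ascending, **unsorted**, or **aggregated**
into the peers' geometric mean. Writing `M` for the log of that geometric
mean (normalised by `T`), the second estimate is the barycentre

    X_s = (1 − S) X_p + S M,

which defines the *sensitivity to social influence*
`S = (X_s − X_p)/(M − X_p)`. Its distribution is a **hurdle law**: a
point mass at `S = 0` (probability `P_0 = 1 − P_g`, "keep my estimate")
plus a Gaussian of mean `m_g` and s.d. `σ_g`. The agent model draws `S`
from this law with

    ⟨S⟩(τ, D) = α_∞ − (1 − ε)^(τ−1) (α_∞ − α_1) + β_± |D − D_0|,
    P_g(τ, D) = ⟨S⟩(τ, D) / m_g(τ)   (clipped to [0, 1]),

where `D = M − X_p` is the distance between the social information and
one's own estimate: mean sensitivity is V-shaped in `D` (the *distance
effect*, with vertex `D_0` and side slopes `β_−`, `β_+`) and saturates
exponentially in `τ` at a rate `ε` shared by `m_g`, `σ_g`, `P_g` and `α`.
The ten parameters per treatment ship as presets
(`crowdwise/presets/*.json`).

The fitting side of the package recovers these quantities from record
tables: the `[−1.05, 2.05]` restriction window for `S`, per-condition
hurdle fits (maximum likelihood or binned least squares), simultaneous
shared-rate saturation fits, the moving-bin cusp fit (bins of width 1,
centres −2…2 in steps of 0.1, weighted least squares with a closed-form
solution at each candidate vertex on a `D_0` grid), collective accuracy
`|median(X)|` and individual accuracy `median(|X|)` with `D`-sign and
`S`-median stratifications, and question-level bootstrap error bars.

## Worked example

```python
import crowdwise as cw

questions = cw.generate_questions(42, seed=0)
design = cw.build_design(seed=0)           # 18 groups of 12, 42 questions
params = cw.load_presets()                 # sorted / unsorted / aggregated
sim = cw.simulate(design, questions, params, n_runs=50, seed=0)
kept, excluded, undefined = cw.restrict_sensitivities(sim.records)
print(f"records: {len(sim.records)}  excluded: {excluded:.4%}  undefined: {undefined:.4%}")

hurdle = cw.fit_hurdle_by_condition(kept)
agg = cw.fit_saturation(hurdle[hurdle["treatment"] == "aggregated"])
print(f"aggregated: epsilon={agg.epsilon:.3f}  m_g(1)={agg.mg1:.3f}  m_g(inf)={agg.mg_inf:.3f}")

cusps = cw.fit_cusp_by_condition(kept[kept["treatment"] == "sorted"])
d0, bm, bp = cw.summarize_constants(list(cusps.values()))
print(f"sorted cusp: D0={d0:.3f}  beta-={bm:.3f}  beta+={bp:.3f}")

acc = sim.accuracy_summary
print(acc[(acc["treatment"] == "aggregated") & (acc["tau"] == 11)].round(3).to_string(index=False))

ci = cw.bootstrap_ci(kept[kept["treatment"] == "aggregated"],
                     lambda f: float(f["sensitivity"].mean()), n_exp=1000, seed=0)
print(f"mean S (aggregated) = {ci.x0:.3f}  (-{ci.b_minus:.3f}, +{ci.b_plus:.3f})")
```

Output:

```
records: 453600  excluded: 0.0053%  undefined: 0.0000%
aggregated: epsilon=0.379  m_g(1)=0.410  m_g(inf)=0.551
sorted cusp: D0=-0.715  beta-=0.104  beta+=0.089
 treatment  tau    phase  collective  individual
aggregated   11 personal       0.282       0.530
aggregated   11   second       0.276       0.434
mean S (aggregated) = 0.393  (-0.003, +0.003)
```

Reading: 50 simulated experiments yield 453 600 estimate records, almost
none outside the `S` window. Refitting the simulated Aggregated data
recovers the generating saturation parameters (`ε = 0.39`,
`m_g(1) = 0.41`, `m_g(∞) = 0.55`) closely; the Sorted cusp vertex comes
back near its generating `D_0 = −0.67` with the slopes slightly
compressed by the bin-width-1 smoothing (see `docs/methods.md`). After
social information sharing at `τ = 11`, individual accuracy improves
from 0.53 to 0.43 orders of magnitude while collective accuracy barely
moves — convergence toward the peer mean helps individuals much more
than it moves the crowd's median. The last line is a question-resampling
bootstrap error bar on mean `S`.

The same stages are scriptable from a shell:

```
crowdwise simulate --preset aggregated --runs 50 --seed 7 --out records.csv
crowdwise fit sensitivity --in records.csv --out fits.json
crowdwise fit cusp --in records.csv --treatment aggregated --out cusp.json
crowdwise analyze accuracy --in records.csv --out accuracy.csv
crowdwise run-all --out artifacts/            # full pipeline + manifest
```

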