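# mangosoft

Kinetic modelling and estimation of mango firmness loss under storage
temperature and ethylene.

Imported mangoes ('Keitt', 'Kent') spend weeks in refrigerated containers
and are then ripened toward a "ready to eat" firmness target. Predicting
when a batch gets there — and explaining why fruit within a batch diverge —
needs a softening model that carries the effects of storage temperature and
the fruit's ethylene state. `mangosoft` implements such a model for acoustic
firmness-index data, together with the hierarchical (indexed) nonlinear
least-squares machinery to estimate its parameters from repeated
single-fruit measurements, and a seed-controlled synthetic-data generator
with the same batch structure for validating every estimation pathway.

## The model

Firmness *F* (acoustic firmness index, FI = f²·m^(2/3)/10⁴ from the second
resonance peak *f* in Hz and mass *m* in kg) is degraded by a pool of
cell-wall-degrading enzymes *Enz* that a constant ethylene signal *Eth*
induces and that turns over with first-order decay:

    d[Eth]/dt = 0
    d[Enz]/dt = k_enz·[Eth] − k_d·[Enz],        Enz(0) = Enz₀
    d[F]/dt   = −k_f·(F − F_fix)·[Enz],         F(0)   = F₀

*F_fix* is the residual firmness a fully soft fruit approaches. Every rate
constant follows Arrhenius' law, k(T) = k_ref·exp((E/R)(1/T_ref − 1/T)),
with T_ref = 295.15 K. Because the enzyme pool starts at zero (ripening is
inhibited on the tree; chilled transport resets it), k_f and k_enz only
appear as a product and are lumped into k_fenz, giving the closed form

    F(t) = F_fix + (F₀ − F_fix)·exp( k_fenz·Eth·((1 − e^(−k_d t))/k_d² − t/k_d) )

at constant temperature. The product **EF = k_fenz(T_mean)·Eth** — the
*ethylene factor* — is the identifiable, unit-free-Eth summary of how fast a
sub-batch's enzyme system responds to ethylene at its mean storage
temperature.

Estimation follows a staged attribution of variation: all parameters in
common first, then *F_fix*/*Eth*/*Enz₀* per batch (fixing Enz₀ = 0 once its
estimates are indistinguishable from zero), then *F₀* per fruit, and
optionally *Eth* per fruit. Standard errors are Gauss–Newton; fit quality is
reported as adjusted R² ("percentage variance accounted for").

## Worked example

Compute the ethylene factor of an untreated 'Keitt' sub-batch stored 16 d
at 20 °C whose batch-level Eth estimate is 2.23:

```
$ mangosoft ef --cultivar Keitt --eth 2.23 --scenario "16:20"
0.138
```

(k_fenz drops from 0.099 at 22 °C to 0.0617 mol⁻¹ d⁻¹ at 20 °C; times
Eth = 2.23 that gives EF = 0.138 d⁻¹-scaled — the fruit's enzyme system
responds about seven times faster than in a sub-batch with EF ≈ 0.02.)

Simulate a fruit moved from 18 °C to 22 °C after 3 days:

```
$ mangosoft predict --cultivar Keitt --f0 60 --f-fix 12.7 --eth 1.52 \
      --scenario "3:18,10:22" --times "0:12:2"
time_d,firmness_fi
0.0,60.0
2.0,55.457
4.0,44.488
6.0,29.351
8.0,19.438
10.0,15.008
12.0,13.41
```

Firmness falls sigmoidally from 60 FI toward the 12.7 FI asymptote — slowly
at first while the enzyme pool builds up, then rapidly, then flattening as
the fruit approaches full softness.

Generate a synthetic four-temperature 'Keitt' experiment (120 fruit,
Eth = 1.52, F_fix = 12.7, measurement noise 2 FI) and fit it back with the
cultivar kinetics held fixed:

```
$ mangosoft simulate --preset keitt_batch2 --seed 1 --out-dir sim
$ mangosoft fit --measurements sim/measurements.csv --scenarios sim/scenarios.csv \
      --cultivar Keitt --out-dir out
$ head -6 out/estimates.csv
parameter,level,label,estimate,se
eth,batch,b2_10C,1.61276,0.113941
eth,batch,b2_17C,1.5094,0.038648
eth,batch,b2_24C,1.50928,0.0255938
eth,batch,b2_30C,1.49448,0.0349027
f_fix,batch,b2_10C,13.9319,2.79774
```

The per-batch Eth estimates recover the generating value 1.52 within their
standard errors (the cold 10 °C batch softens little in 16 days, hence its
wider interval), and `out/ef.csv` turns each estimate into an ethylene
factor at that batch's storage temperature. The same workflow is available
as library calls (`generate`, `fit`, `staged_fit`, `ef_table`).

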