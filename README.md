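# sociorank

Social-network and dominance-hierarchy analysis of ethogram-coded dyadic
behavior logs in cattle.

Confined cattle establish a dominance hierarchy through agonistic
encounters (mounting, fighting, headbutting) and maintain social bonds
through affiliative contact (head-play). `sociorank` is for behavioral and
welfare researchers who record such interactions as long-format event logs
(one row per observed interaction: period, session, author, receptor,
behavior) and want, per behavioral category and observation period:

* **directed weighted interaction networks** with the full parameter
  panel: density, connections, mutual/asymmetric/null dyad census,
  reciprocity, diameter, betweenness, closeness, weighted in/out/all
  degrees, and mutually-reinforcing hub ("Authors") and authority
  ("Receptors") scores;
* **balance-index hierarchy ranks** and pre/post rank deltas, where

  ```
  BI = [(IN_aff + 0.005) / (IN_ag + 0.001)] / [(OUT_aff + 0.005) / (OUT_ag + 0.001)]
  ```

  combines the frequencies with which an animal received (IN) and authored
  (OUT) affiliative and agonistic behavior; rank 1 goes to the largest BI,
  and Δ = rank_pre − rank_post is positive for animals that ascend;
* the **inference layer**: paired and unpaired two-tailed Wilcoxon tests,
  Spearman correlation, multiple logistic regression on the dichotomous
  rank outcome (downgraded vs ascended), a small-sample-exact permutation
  test for single model terms, and standardized PCA;
* a **synthetic-herd generator** with a planted dominance hierarchy and an
  inflammation-displaces-rank effect, so every stage is testable without
  animal data.

See `docs/methods.md` for the model, conventions and known limitations.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
14-bull herd (run them in order; outputs land under `results/`):

```sh
python analysis/01_simulate_herd.py
python analysis/02_build_networks.py
```

prints the graph-level panel of the four networks:

```
             agonistic_pre  agonistic_post  affiliative_pre  affiliative_post
density               0.51            0.30             0.25               0.1
asym                 52.00           52.00            37.00               9.0
null                 19.00           38.00            50.00              36.0
diameter              4.00            5.00             4.00               4.0
connections          92.00           54.00            45.00               9.0
reciprocity           0.43            0.04             0.18               0.0
n_active             14.00           14.00            14.00              10.0
agonistic: connections 92 -> 54, density 0.51 -> 0.30, reciprocity 0.43 -> 0.04
affiliative: connections 45 -> 9, density 0.25 -> 0.10, reciprocity 0.18 -> 0.00
```

Castration reduces both the number and the reciprocity of interactions;
only 10 of 14 bulls still engage in affiliative contact afterwards (the
density denominator shrinks accordingly — the active-node convention).
`analysis/03_rank_hierarchy.py` then ranks the herd by balance index and
reports, for this herd, that the bulls that failed to ascend carry a higher
mean inflammation score than the ascenders (1.43 vs 0.71);
`analysis/04_run_inference.py` runs the period comparisons, the logistic
models, the Δ–inflammation Spearman correlation and the PCA; and
`analysis/05_recovery_calibration.py` checks the pipeline against the
generator's planted truth over 200 independent herds:

```
                                 metric    value   n
              type1_rejection_rate_null 0.040000 200
positive_coefficient_rate_strong_effect 0.814815 189
      strong_signal_recovery_rho_median 0.736264  15
```

With no planted effect the inflammation term is declared significant in
4% of herds (nominal 5%); under a strong effect the coefficient is
positive in ~81% of converging fits — limited by balance-index rank
measurement noise, not by the fitting (see `docs/methods.md`); and under a
near-deterministic hierarchy the BI ranking recovers the planted order
with median ρ ≈ 0.74.

The same pipeline runs from the shell on your own data:

```sh
sociorank simulate --seed 7 --out herd/          # or bring your own CSVs
sociorank validate --events herd/events.csv
sociorank run --events herd/events.csv --covariates herd/covariates.csv --out report/
```

Event logs are CSV with columns `period,session,author,receptor,behavior`;
covariates are CSV with columns
`id,period,weight_kg,adg_kg_day,testosterone_pg_ml,inflammation_score,surgery_order`.

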