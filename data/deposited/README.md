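# Deposited per-animal source data

Place the per-animal source-data tables of the original study here to enable
the deposited-data statistical checks:

- `params_12mo.csv` — estimated model parameters of the 12-month-old group,
  one row per animal, columns: `animal_id, genotype` (control / appnlgf) and
  `alpha, g, eta, max_em_iter, w0, sigma_r2, sigma_x2, theta, lam, K`.
- `params_6mo.csv` — same schema for the 6-month-old group.
- `freezing.csv` — per-animal freezing percentages, columns:
  `animal_id, age, genotype, precs_test3, cs_test3, di_test3_test1`.

These tables are distributed as the figure source-data files of the original
publication and are not bundled with this package.
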