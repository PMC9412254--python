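# germniche

Population-based threshold modelling of the seed germination thermal
niche. The package simulates and fits germination time-courses across
dormancy stages, quantifies dormancy release during dry after-ripening,
measures germination synchrony, and predicts germination timing from
long-term monthly mean temperatures.

## What it does

- **model**: germinable fraction at a temperature from normally
  distributed lower/higher limit thresholds (`Tl50`/`Th50` with spreads);
  thermal-time accumulation above the base temperature (sub-optimal) or
  below the maximum (supra-optimal); cumulative germination time-courses;
  classification of the dormancy pattern (Type 1/2/3) from how the
  permissive window changes across stages.
- **fitting**: joint estimation of window and thermal-time parameters
  from multi-temperature censuses by RMSE minimisation (bounded
  least-squares with seeded Latin-hypercube multi-start). Censuses at
  30 °C are excluded before fitting.
- **afterripening**: thermal after-ripening time (°C·hour above a
  lower-limit storage temperature) and the rate of widening of the
  thermal niche (RWTN = 1/slope of the OLS fit of `Th50` on storage
  hours, with SE, F-test p-value and R²).
- **synchrony**: the SOG statistic — RMS deviation of simulated
  percentile-level values from the observed mean (with a paired-RMS
  alternative behind `mode="paired"`).
- **niche**: stage-indexed thermal-niche envelopes, overlap tests, and
  germination-timing prediction by scanning a piecewise-linear
  interpolation of monthly means forward from seed maturity.
- **simulate**: binomial census generation with monotone cumulative
  counts, `Th50` trajectories, and sinusoidal climate series for
  fully offline validation.

Reference per-stage parameters for nine populations and the expected
niche-widening regression results ship as plain-CSV fixtures under
`src/germniche/data/`.

## CLI

```sh
germniche generate --truth params.csv --cardinals cardinals.yaml --out counts.csv --seed 1
germniche fit --counts counts.csv --cardinals cardinals.yaml --out fitted.csv --seed 1 --starts 8
germniche rwtn --params fitted.csv --hours "M=0,AR1=720,AR2=1440,AR5=3600" --out rwtn.csv
germniche sog --counts counts.csv --fitted fitted.csv --cardinals cardinals.yaml --out sog.csv
germniche niche-plot --params fitted.csv --cardinals cardinals.yaml --climate climate.csv --out niche.png
germniche predict-timing --params fitted.csv --cardinals cardinals.yaml --climate climate.csv --maturity-month 7 --out timing.csv
germniche run --config config.yaml   # full pipeline
```

File formats: counts CSV
(`population,stage,temp_c,replicate,day,germinated,total`), parameter CSV
(`population,storage_month,stage,Tl50,sigma_Tl,Th50,sigma_Th,theta_sub50,sigma_sub,theta_sup50,sigma_sup,R2`),
climate CSV (`month,mean_temp_c`), and a YAML map of cardinal
temperatures per population (`Pop: {Tb: …, To: …, Tm: …}`). A pipeline
config YAML names `counts`, `cardinals`, `climate`, `out_dir`, `seed`,
`n_starts`, `sog_mode` and `maturity_month`.

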