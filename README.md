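# wfdisp

Displacement analysis of marine top predators at offshore wind farms from
boat-based line-transect surveys.

Offshore wind farms may displace seabirds and cetaceans from the habitat
inside and around a development's footprint. Monitoring programmes run
repeated vessel surveys across the preconstruction, construction and
operational phases and ask: did relative abundance change inside the
footprint, beyond what the site-wide spatial and temporal variability can
explain? `wfdisp` implements that analysis end-to-end for two archetypal
species — common guillemot (*Uria aalge*) and harbour porpoise (*Phocoena
phocoena*) — and is aimed at ecological statisticians and consultants doing
before–after impact assessments of marine developments.

## The models

Survey tracks are projected to UTM and chopped into fixed-length segments
(600 m for guillemot, 1 km for porpoise); sightings are assigned to segments
by time-interpolated position and summed. Segment counts are then modelled
hierarchically:

**Guillemot** — negative binomial GAMM, log link:

```
y_i ~ NB(mu_i, theta),            Var(y_i) = mu_i + mu_i^2 / theta
log mu_i = beta_phase(i) + f_phase(i)(x_i, y_i) + b_survey(i)
           + c_transect(i) + log(effort_i / 600 m)
```

**Harbour porpoise** — zero-inflated Poisson GAMM; the binary part absorbs
excess zeros from sampling error, availability and sea-state-dependent
detectability:

```
P(y_i = 0)  = pi_i + (1 - pi_i) exp(-mu_i)
logit pi_i  = gamma_0 + gamma_cond [sea state poor]
```

`f_phase` is a low-rank thin-plate spatial smooth with a separate surface
per development phase, and survey / transect-within-survey are nested random
effects. Everything is fitted by MCMC (an in-package No-U-Turn sampler with
analytic gradients), with split R-hat and ESS diagnostics. From the fit the
package predicts relative-abundance surfaces per phase on a fine grid,
and flags cell-wise change between phases where the two 95% credible
intervals do not overlap — the conventional mapping rule for displacement
asterisks.

A synthetic-survey generator reproduces the whole study design (10 parallel
18 km transects 2 km apart, three phases, GPS fixes every 30 s, Beaufort
records every 15 min, NB/ZIP counts over latent Gaussian-process intensity
surfaces, optional displacement effect inside the footprint) so every stage
is testable against known ground truth.

## Worked example

Simulate a monitoring programme in which construction reduces guillemot
intensity inside the footprint by 70%, then run the full pipeline:

```sh
wfdisp simulate --scenario displacement-test --reduction 0.7 --seed 1 --out survey/
wfdisp run --track survey/track.csv --sightings survey/sightings.csv \
    --seastate survey/seastate.csv --phases survey/phases.csv \
    --footprint survey/footprint.geojson --species guillemot \
    --chains 2 --warmup 300 --draws 300 --knots 25 --seed 1 --out run/
```

`run/parameter_table.txt` then contains (numbers from this exact invocation,
about two minutes on one CPU):

```
                          parameter  raw_estimate  raw_lo  raw_hi  response_estimate  response_lo  response_hi significant
Preconstruction versus construction        -0.196  -0.497   0.134              0.822        0.608        1.143          No
      Construction versus operation         0.263  -0.040   0.590              1.301        0.960        1.803          No
   Preconstruction versus operation         0.067  -0.199   0.381              1.070        0.820        1.464          No
```

Reading: site-wide phase effects are all non-significant (the raw 95%
credible intervals bound zero) — the displacement is local, not site-wide,
exactly as simulated. The local signal appears in the change maps:
`run/change_preconstruction_vs_construction.csv` flags 60 of the 64
footprint cells as significant negative changes, while
`run/change_preconstruction_vs_operation.csv` flags none, and
`run/footprint_summary.json` puts the construction-phase footprint mean at
0.549 guillemot per segment against 1.690 before construction — a ratio of
0.325, close to the simulated 0.3. Artifacts also include
per-phase surfaces (CSV + GeoJSON), uncertainty maps (posterior SD as a
proportion of the mean), the effort ledger, fit draws and diagnostics, and a
manifest with the seed and config hash; `wfdisp verify --out run/` re-derives
the rendered tables from the stored draws and diffs them.

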