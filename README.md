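# porinflux

Quantification of porin-mediated solute transport across polymersome
membranes, read out by an encapsulated *Gaussia* luciferase (GLuc)
reporter.

## The problem

Porins — trimeric β-barrel channels such as OmpF and PhoE from
*E. coli* — control passive solute influx across the Gram-negative
outer membrane. Measuring their absolute transport rates in whole cells
is confounded by cellular background; a bottom-up alternative
reconstitutes purified porins into polymersomes (vesicles of
PMOXA–PDMS–PMOXA triblock copolymer with a thick, ~14 nm,
low-permeability membrane) that encapsulate GLuc. When the luciferase
substrate coelenterazine (CLZ) is injected outside, light is emitted
only as fast as substrate crosses the membrane: the free enzyme's
flash kinetics turns into a transport-limited glow, and the luminescence
level reports the flux through the reconstituted porins.

`porinflux` implements the full quantification chain for this assay,
plus a mechanistic forward simulator and seeded synthetic-data
generators that stand in for raw plate-reader exports.

## The model

**Geometry.** For a batch with z-average diameter $d_P$ and membrane
thickness $r_M$, the lumen volume is
$V_{P,i} = \tfrac{4}{3}\pi (d_P/2 - r_M)^3$, and statistical
encapsulation of an applied enzyme concentration $c_{GLuc}$ gives
$N_{GLuc,i} = V_{P,i}\, c_{GLuc}\, N_A$ enzymes per vesicle (a mean,
kept fractional). The total encapsulated amount in a well is
$n_{GLuc,P} = c_{GLuc}\, V_{P,i}\, N_P\, V_E$ and the correlation factor
$F_C = n_{GLuc,C}/n_{GLuc,P}$ maps vesicle-well intensities onto the
free-enzyme calibration gauge.

**Calibration.** Free-enzyme flash traces are fitted to
$y = a\,e^{-k_1 t} + b$ and extrapolated to the 1 s peak (sampling
starts only at 2 s). Peak intensity versus substrate concentration
follows a Hill model,

$$v(c_S) = \frac{v_{max}\, c_S^{\,h}}{K_{0.5}^{\,h} + c_S^{\,h}},$$

fitted by unweighted nonlinear least squares with bootstrap CIs, and
inverted as $c_S = K_{0.5}\,(v/(v_{max}-v))^{1/h}$.

**Transport rate.** At quasi-steady state the porin influx equals the
enzymatic consumption, so after control subtraction and gauge
correction the per-trimer rate is

$$k_{transport} = k_{cat}\,\frac{N_{GLuc}}{n_{tri}}\,
\frac{c_S^{\,h}}{K_{0.5}^{\,h}+c_S^{\,h}},$$

valid below the assay-sensitivity bound
$\bar N_{GLuc}\,k_{cat} > k_{transport}$. SEMs combine the relative
errors of trimer densitometry, vesicle concentration and (for substrate
derivatives) the quantum-yield factor in quadrature; rates of CLZ
derivatives are rescaled by their relative quantum yield (13.9 for
CLZ-n, 11.7 for CLZ-I) before inversion.

## Worked example

Generate a synthetic dataset under the reference batch conditions
(5% replicate CV, triplicates), calibrate, and infer:

```python
from porinflux.datasets import make_calibration_dataset, make_assay_dataset, default_scenarios
from porinflux.pipeline import (batch_config_from_reference, calibrate_from_table,
                                format_report, infer_transport_table)

cal_df, _ = make_calibration_dataset(noise_cv=0.05, seed=11)
hill = calibrate_from_table(cal_df, n_bootstrap=0)
assay_df, _ = make_assay_dataset(default_scenarios(noise_cv=0.05), seed=11)
batches = {n: batch_config_from_reference(n)
           for n in ("control", "OmpF", "OmpFdelta", "PhoE")}
print(format_report(infer_transport_table(assay_df, hill, batches, control="control")))
```

prints

```
per-trimer transport rates
------------------------------------------------------------
      OmpF / CLZ    k =  10.92 +/- 1.58 s^-1  (c_S = 1.3 uM, bound 47 s^-1)
 OmpFdelta / CLZ    k =  77.00 +/- 13.81 s^-1  (c_S = 0.859 uM, bound 90 s^-1)
      PhoE / CLZ    k =   2.72 +/- 0.46 s^-1  (c_S = 0.907 uM, bound 66 s^-1)
```

with the fitted calibration `v_max = 1.161e+08 a.u., K_0.5 = 9.96 uM,
h = 1.48, r2 = 0.9982` for this seed. Each rate is the inferred number
of substrate molecules per second passing one porin trimer; `c_S` is the
steady-state lumen concentration the enzyme sees, and `bound` the
enzymatic-capacity ceiling below which the readout is transport-limited.
The generating truths here were 10.8, 78.0 and 2.8 s⁻¹.

The same chain is available from the shell:

```sh
porinflux simulate --seed 11 --out sim/
porinflux calibrate --traces sim/calibration.csv --bootstrap 1000 --out hill.yaml
porinflux infer --config run.yaml --calibration hill.yaml --out results.tsv
porinflux report --results results.tsv
```

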