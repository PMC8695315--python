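# Methods

## Rate model

The per-snapshot ET rate is the Marcus–Kakitani–Mataga form

    k(t) = ν₀ / (1 + exp[β(Rc(t) − R₀)]) · exp[ −(ΔG⁰(t) + λ(t))² / (4 λ(t) k_B T) ]

in ps⁻¹. The sigmoidal factor interpolates between the adiabatic regime
(Rc ≪ R₀, gate ≈ 1) and the nonadiabatic tunnelling regime (Rc ≫ R₀, gate
≈ exp[−β(Rc − R₀)], the classical linear Dutton decay of ln k with
distance). The Gaussian factor is the classical Marcus Franck–Condon term;
no quantum-mode (Marcus–Jortner) correction and no explicit
√(1/(4πλk_BT)) normalization is included — any constant factor is absorbed
into ν₀, and nothing downstream (peak locations, law classification)
depends on it.

The free-energy gap decomposes as

    ΔG⁰(t) = (E_IP − E_EA) − C_e/(ε₀^DA · Rc) + E_net(t)

with the donor ionization potential E_IP, the acceptor (Iso*) electron
affinity E_EA (shiftable to model the emission-wavelength dependence of
the accepting state), the donor-cation/acceptor-anion Coulomb
stabilization, and the point-charge sum E_net over ionic residues, each
charge interacting with the acceptor anion (−1 e) and donor cation (+1 e)
screened by a single dielectric constant. The sign convention: favourable
ET has ΔG⁰ < 0, and all laws are plotted against −ΔG⁰ (written −SFEG).

λ(t) is the Marcus two-sphere continuum expression evaluated at the
snapshot distance. It is strictly increasing in Rc and positive whenever
1/(2a_D) + 1/(2a_A) > 1/Rc and ε_∞ < ε₀ (violations abort with a domain
error rather than producing a negative width in the Franck–Condon factor).

### Constants and units

eV / nm / ps / K everywhere; conversions only at I/O boundaries.
C_e = e²/(4πϵ₀) = 1.439964 eV·nm; k_B = 8.617333×10⁻⁵ eV/K; default
T = 298 K.

### Parameters

ν₀, β, R₀, the radii and the dielectric constants are system-specific and
not derivable from the shipped tables; the defaults
(ν₀ = 1000 ps⁻¹, β = 14 nm⁻¹, R₀ = 0.6 nm, a_D = a_A = 0.25 nm, ε_∞ = 2,
ε₀ = 5, ε₀^DA = 2) are illustrative placeholders for exercising the model,
not fitted values for any flavoprotein. They are loadable from JSON/TOML
config with unit-suffixed keys (`nu0_per_ps`, `beta_per_nm`, ...); unknown
keys are rejected.

## Synthetic trajectories

The generator emulates the statistical structure of MD-derived snapshot
series, not their physics:

* **Rc(t)** is a stationary AR(1) Gaussian process with specified mean,
  marginal sd and lag-1 autocorrelation, clipped from below (clipping, not
  rejection, keeps the series length exact). AR(1) is the simplest
  stationary process with tunable memory; defaults (mean 0.72 nm,
  sd 0.03 nm, autocorrelation 0.8) sample roughly 0.64–0.80 nm like the
  fast donors being emulated.
* **−SFEG(t)** is generated directly from the empirical linear
  distance–energy coupling, −SFEG = C + B·Rc + ε with B = −0.5 eV/nm and
  snapshot noise sd 0.02 eV by default, rather than from explicit charges:
  this gives the generator exact ground truth (the line, λ(Rc̄), the
  implied energy-peak location) against which fits are tested.
  Charge-based gap evaluation remains available through the core module.
  The intercept is chosen so the ensemble-mean −SFEG lands on a requested
  window: explicitly via `neg_sfeg_mean`, via the electronic gap `dg_e`
  (mean = −dg_e + Coulomb at Rc̄), or by default on λ(Rc̄) — the
  energy-gap-law vertex, i.e. the ultrafast regime.
* **Generator rate parameters** place the adiabatic crossover at
  R₀ = 1.0 nm, beyond the sampled distance window, so the distance gate is
  saturated across the ensemble. This is the regime the ultrafast donors
  occupy: with R₀ inside the window the gate contributes a steep
  linear-in-Rc term that pushes the observable ln-rate maximum far outside
  the sampled −SFEG window, whereas the donors being emulated show their
  maxima *inside* it. The nonadiabatic tail (and the classical Dutton
  slope −β) is still exercised directly through the core rate function.
* Seeds are mandatory; there is no global random state, and every derived
  stream (distance series, gap noise) is spawned deterministically from
  the spec seed.

What passing tests on these ensembles show: that the fitting and
peak-mapping machinery recovers known ground truth under realistic
dynamic ranges, autocorrelation and noise. What they do not show:
anything about force-field energetics, hydrogen-bond dynamics, or the
actual parameter values of any protein.

## Law fitting and classification

All fits are unweighted ordinary least squares (the source tables state no
weighting scheme). R² = 1 − SS_res/SS_tot is reported as-is, including
negative values for fits worse than the mean.

Shape classification of a distance law is necessarily a judgment call in
the source material; the implemented rule is: *parabolic* when the
quadratic term passes a partial F-test at α = 0.05 **and** curvature is
downward **and** the vertex lies within the observed x-range extended by
half its width on each side (a peak the data can actually resolve);
otherwise *linear* when the line's R² ≥ 0.2; otherwise *no clear
relation*. All three thresholds are exposed as configuration.

Region partition: on the energy axis a snapshot is *inverted* when
−SFEG > X_m(ES); on the distance axis when Rc < X_m(Rc). Values exactly at
the threshold count as normal (an arbitrary but fixed convention; the
boundary case is measure-zero for real data).

## Peak mapping and rounding order

X_m(ESRc) = B₃·X_m(Rc) + C₃ evaluates the ESRC line at the distance peak;
the inverse mapping X_m(Rc) = (X_m(ES) − C₆)/B₆ back-evaluates a distance
peak for linear-Dutton donors. The pipeline never rounds intermediates:
because the ESRC slopes are shallow (|B| ≈ 0.4–0.6 eV/nm), feeding a
two-decimal-rounded energy peak through the inversion displaces the result
by a display ulp or more (e.g. 72.2/(2·21.4) = 1.6869 → 0.54 nm, but the
rounded 1.69 → 0.53 nm). Two-decimal display values exist only in report
columns. The default peak-agreement tolerance is 0.10 eV, a quantification
of the verbal "quite close" standard in the source analysis;
back-evaluated peaks below the sampled Rc minimum are flagged as
extrapolations.

For donors sampling two conformations, the ESRC fit accepts an optional
per-donor Rc cutoff rather than an automatic split rule (no split
criterion is documented in the source material).

## Table fixtures

The three published coefficient tables are shipped as CSV with every cell
kept as its printed string. Derived columns are recomputed in exact
decimal arithmetic (`decimal.Decimal` on the printed strings) and compared
at two-decimal display precision with banker's rounding — decimal
arithmetic matters: in binary floats −0.45·0.81 + 2.83 = 2.4654999…,
which would silently round the wrong way. Five cells are internally
inconsistent with their own printed coefficients (three energy peaks that
coincide with the corresponding *distance* peaks, suggesting a column
transcription slip, and two mapped peaks off by one display ulp); they are
flagged and annotated, and strict verification fails only on unannotated
mismatches. Where the running text and a table disagree on a coefficient,
the table value is canonical — in every such case it, and not the text
variant, reproduces the printed derived cell.

## Problem sizes and numerical choices

Synthetic checks use n = 500–1000 snapshots: large enough that the
AR(1)/OLS standard errors put parameter recovery well inside the asserted
tolerances, small enough to keep the whole suite around a couple of
seconds. The peak-equivalence check uses rc_sd = 0.010 nm so λ varies
< 5% across the sampled range (λ′(Rc) ≈ 0.83 eV/nm at 0.72 nm), isolating
the linear distance–energy mapping the equivalence argument rests on; the
generator's default rc_sd = 0.03 emulates the wider published ranges.
ln(1 + e^x) is evaluated as logaddexp(0, x) to avoid overflow deep in the
nonadiabatic tail.

## Known limitations

* The rate is classical Marcus; no nuclear tunnelling corrections, so
  deep-inverted-region rates are underestimated relative to quantum
  treatments.
* Rc is taken as a supplied scalar per snapshot (center-to-center for
  synthetic geometry); the aromatic-atom-pair averaging that defines it
  for real structures requires atomic coordinates and is out of scope.
* E_net uses a single screening constant for all charge sites; real
  protein electrostatics are heterogeneous.
* The classification thresholds (α, R² floor) are this package's
  operationalization of a by-inspection judgment; borderline datasets can
  legitimately classify differently under other conventions.
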