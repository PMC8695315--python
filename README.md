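# flavoet

Analysis of ultrafast photoinduced electron transfer (ET) in flavoproteins:
the Marcus–Kakitani–Mataga (MKM) rate model, the three empirical laws that
govern it, and the equivalence between the *energy-gap-inverted* and the
*donor–acceptor-distance-inverted* regions.

## The problem

When a flavin's isoalloxazine ring (Iso) is photoexcited, nearby aromatic
residues — typically tryptophans — quench its fluorescence by donating an
electron:

    Iso* + Trp  →  Iso⁻ + Trp⁺        ΔG⁰ (standard free-energy gap, eV)

Per molecular-dynamics snapshot the MKM rate (ps⁻¹) is

    k = ν₀ / (1 + exp[β(Rc − R₀)]) · exp[ −(ΔG⁰ + λ)² / (4 λ k_B T) ]

with donor–acceptor distance Rc (nm), adiabatic/nonadiabatic crossover R₀,
distance-decay coefficient β, and the Marcus two-sphere solvent
reorganization energy

    λ = C_e (1/(2a_D) + 1/(2a_A) − 1/Rc)(1/ε_∞ − 1/ε₀).

Three empirical laws describe snapshot ensembles:

* **SEGL** (energy gap law): ln Rate vs −ΔG⁰ is a downward parabola whose
  vertex X_m(ES) separates the normal from the *energy-inverted* region.
* **EXDL** (extended Dutton law): ln Rate vs Rc — parabolic for ultrafast
  donors (vertex X_m(Rc), below which lies the *distance-inverted* region),
  linear (classical Dutton decay) for slower ones.
* **ESRC**: −ΔG⁰ is approximately linear in Rc, −ΔG⁰ = B·Rc + C.

Because the ESRC line maps the distance axis onto the energy axis, the
distance peak implies an energy peak X_m(ESRc) = B·X_m(Rc) + C. Agreement
of X_m(ESRc) with the directly fitted X_m(ES) shows the two inverted
regions are a single phenomenon seen along two axes — the package's central
analysis. For donors with a *linear* distance law, the implied distance
peak is instead back-evaluated as X_m(Rc) = (X_m(ES) − C)/B and flagged
when it falls below the sampled Rc range.

The package ships the published fit-coefficient tables for four
flavoproteins (FMN-binding protein, wild-type and T169S pyranose
2-oxidase, medium-chain acyl-CoA dehydrogenase; donors Trp32/Trp106/
Trp168/Trp166 in subunits A–D) as machine-readable fixtures, recomputes
every derived peak column in exact decimal arithmetic, and flags the
handful of internally inconsistent printed cells. A seeded synthetic
trajectory generator (AR(1) distance dynamics plus the linear
distance–energy coupling) makes the whole pipeline testable end-to-end
with exact ground truth.

## Worked example

```sh
flavoet simulate --seed 11 --out snapshots.csv --truth-out truth.json
flavoet report --in snapshots.csv
```

prints

```
synthetic TrpXA: distance law parabolic
  X_m(ES)   = 1.1308 eV
  X_m(Rc)   = 0.7131 nm
  X_m(ESRc) = 1.1299 eV  |diff| = 0.0008 eV -> agree at 0.1 eV
```

The generator placed the −ΔG⁰ window on the energy-gap-law vertex
λ(Rc̄) = 1.128 eV (recorded in `truth.json`); the fitted energy peak
(1.1308 eV) and the distance peak mapped through the ESRC line
(0.7131 nm → 1.1299 eV) both recover it and agree to 0.0008 eV — the
peak-equivalence property at desk scale.
`flavoet tables` prints the row-by-row recomputation report for the three
published tables (29/34 rows arithmetic-consistent; the five known
inconsistent cells are annotated). The other subcommands (`rates`, `fit`,
`equivalence`) expose the intermediate pipeline stages on any snapshot CSV
with columns `protein,donor,subunit,time_ps,rc_nm,neg_sfeg_ev`.

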