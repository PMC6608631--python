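# tetrare

Tools for reasoning about the slow self-assembly of the radiopharmaceutical
synthon *fac*-[Re(CO)₃(H₂O)₃]⁺ into the tetranuclear cubane cluster
Re₄(μ₃-OH)₄(CO)₁₂, and for analysing the rhenium binding sites such chemistry
leaves in protein crystal structures.

The package is aimed at radiopharmaceutical and structural chemists who want
to ask two kinds of question:

1. **Kinetics** — if tetranuclear cluster formation is overall fourth order in
   the monomer, how does its half-life respond to metal concentration, and can
   formation outrun the decay of the medically relevant isotopes ¹⁸⁶Re
   (t₁/₂ = 3.7 d) and ¹⁸⁸Re (t₁/₂ = 17 h)?
2. **Structure** — given a coordinate file, which protein atoms coordinate the
   metal (with what uncertainty), which contacts are merely van der Waals, and
   which metal atoms form multinuclear clusters?

## The model

Formation of the di-, tri- and tetranuclear species from the monomer M is
treated at overall orders n = 2, 3, 4. For an nth-order consumption
−d[M]/dt = k[M]ⁿ the half-life is

    t½ = (2ⁿ⁻¹ − 1) / ((n − 1) k c₀ⁿ⁻¹)        (n ≥ 2)

so t½ ∝ c₀^(1−n): at order 4, a tenfold concentration increase shortens the
half-life a thousandfold. A one-year half-life at 30 mM becomes ≈ 8.8 h at
300 mM — inside one ¹⁸⁸Re decay half-life. The same rate constants can drive
a full mass-action ODE network, either stepwise (M+M→D, D+M→T, T+M→Q) or as
parallel empirical sinks, with rhenium mass balance enforced. The aqua
monomer's acid-base speciation uses pKa = 7.5.

On the structural side, a distance d between two atoms of a structure with
Cruickshank diffraction precision index DPI carries σ(d) = √2·DPI. Contacts
classify as coordination (d ≤ covalent sum + 0.8 Å), van der Waals (up to the
vdW limit: Re⋯N 3.7 Å, Re⋯O 3.67 Å) or none; Re⋯Re pairs within 4.3 Å join a
cluster graph whose connected components give nuclearities. The *quasi bite
angle* is the angle subtended at the metal by two atoms of one residue.

A seeded generator emits synthetic PDB fixtures with ground-truth sidecars:
*fac*-Re(CO)₃(H₂O)₂(N-His) adducts, carboxylate-bound lone Re, and the ideal
cubane (Re–Re edge 3.43 Å).

## Worked example

```sh
tetrare simulate --out demo/
```

calibrates k for a one-year target half-life at 30 mM (order 4), integrates
the network, and compares formation with isotope decay. The run prints

```
INFO tetrare: simulate: t1/2=8.77e+03 h, 10x -> 8.77 h
```

and `demo/summary.json` contains (abridged):

```json
{
 "calibrated_k": 9.8585,            // L^3 mol^-3 h^-1
 "analytic_half_life_h": 8766.0,    // one year at 30 mM, by construction
 "scaled_half_life_h": {"1x": 8766.0, "10x": 8.766},
 "simulated_formation_half_time_h": 8766.29,
 "feasibility": [
   {"nuclide": "188Re", "concentration": "1x",  "ratio": 515.65, "verdict": "inaccessible"},
   {"nuclide": "188Re", "concentration": "10x", "ratio": 0.516,  "verdict": "accessible",
    "fraction_remaining": 0.699}
 ]
}
```

Reading: at 30 mM the cluster needs ~516 ¹⁸⁸Re half-lives to form (hopeless);
at 300 mM it forms in half an isotope half-life, with 70% of the activity
still present — concentration manipulation alone makes the cluster
accessible. The ODE half-time (8766.3 h) agrees with the analytic value.

Structure side:

```sh
tetrare fixtures --seed 7 --out fx/          # His adduct + cubane, truth sidecar
tetrare analyze --pdb fx/fixture.pdb --dpi 0.018 --out out/
```

`out/clusters.csv` lists one nuclearity-4 cluster (six formal Re–Re edges at
3.43 Å) and the lone His-bound Re; `out/contacts.csv` contains the Re–NE2
coordination bond at 2.16 ± 0.025 Å (σ = √2 × 0.018).

```sh
tetrare anomalous --f2-opt 12.1 --f2-ref 5.9
```

reports the anomalous peak-height enhancement 2.05 (printed 2.1 at one
decimal) gained by collecting at the Re L_I edge instead of Cu Kα.

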