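# gcrsim

Design toolkit for ground-based galactic cosmic ray (GCR) simulation at an
ion accelerator.

Astronauts beyond low Earth orbit are chronically exposed to a mixed field
of protons, helium and heavier ions (HZE, Z ≥ 3). Behind typical
spacecraft shielding and body self-shielding, that field — the *reference
field*: the blood-forming-organ spectrum behind 20 g/cm² of aluminum at
solar minimum — can be approximated on the ground by a sequence of
monoenergetic accelerator beams. `gcrsim` re-creates that design chain for
radiobiology study planning:

1. **Ion physics** — Bethe–Bloch electronic stopping power with the
   Sternheimer density-effect correction and a Barkas-type effective
   charge, CSDA ranges by integration of 1/S(E), and range–energy
   inversion for degrader calculations (protons to iron, 1–2500 MeV/n, in
   water / polyethylene / aluminum).
2. **Reference field** — containers and integrals for the shielded-tissue
   spectra: absorbed dose via D[Gy] = 1.602·10⁻⁹ Φ L/ρ, ICRP-60 quality
   factor Q(L), dose equivalent, traversals per cell nucleus, the 1.85
   solar-cycle flux scale, plus a self-calibrating synthetic field
   generator.
3. **Beam selection** — energy bins (geometric-mean interior edges, 0
   lower edge, 50 GeV/n upper edge) for protons and helium, five
   log-spaced LET bins on [2, 200] keV/μm for the HZE beams, and the
   fluence-weighted dose table normalized to a target dose: the 33-beam
   full design and the simplified 5-ion field.
4. **Delivery planning** — binary-filter (0.1…12.8 cm polyethylene
   doubling set) decomposition, the commissioned delivery order with
   accelerator-switch accounting (21 switches for the 33-beam sequence),
   and equal-fraction scheduling on a 6-days-per-week calendar with the
   0.1 mGy minimum-fraction flag.
5. **Phantom dosimetry** — synthetic mouse/rat voxel phantoms and
   straight-line CSDA ray-cast irradiation to check dose homogeneity
   (organ means, skeleton signature, voxel spread).

## Worked example

Design a 500 mGy exposure from the built-in synthetic reference field,
order it for delivery, and fractionate it over four weeks:

```sh
$ gcrsim design --dose 500 --out t.csv
33 beams, 500 mGy -> t.csv

$ gcrsim order --table t.csv | head -5
 1  1H     1000.0 MeV/n    56.340 mGy
 2  4He    1000.0 MeV/n     8.626 mGy
 3  28Si    600.0 MeV/n     5.144 mGy
 4  1H       20.0 MeV/n     2.884 mGy
 5  1H       23.3 MeV/n     1.850 mGy

$ gcrsim order --table t.csv | tail -1
switches: 21 (canonical order)

$ gcrsim schedule --table t.csv --fractions 24
daily total 20.8 mGy over 27 calendar days -> schedule.csv
```

The table opens with the relativistic proton beam and closes with the
250 MeV proton beam; heavy ions are interleaved between light-ion blocks;
consecutive degraded beams share one 100 MeV/n accelerator setting, so the
33 beams need only 21 ion–energy switches. Splitting 500 mGy into 24
fractions gives the 20.8 mGy daily total used in chronic study designs.

Physics queries work the same way:

```sh
$ gcrsim physics let 56Fe 600        # LET in water, keV/um
172.31
$ gcrsim physics range 1H 100        # CSDA range in water, cm
7.711
$ gcrsim degrader 7.36               # binary-filter decomposition
sheets: 0.2, 0.8, 6.4 -> 7.4 cm
```

and a homogeneity check of the designed table in the synthetic mouse:

```sh
$ gcrsim phantom irradiate --table t.csv --out organ_doses.csv
organ average 520.8 mGy; 95%-within-15%: True -> organ_doses.csv
```

`gcrsim run` executes the whole pipeline and writes a provenance-stamped
bundle (beam table, sequence, schedule, JSON provenance record);
re-running the same configuration reproduces every artifact byte for
byte.

## Scope and limitations

Transport is continuous-slowing-down only: no nuclear fragmentation,
lateral scattering or secondary-particle buildup, so phantom organ doses
are a homogeneity check, not a Monte Carlo replication (see
`docs/methods.md` for a quantitative discussion). The stopping model
omits shell corrections and higher-order (Mott/Bloch) terms; accuracy
against the published beam table is ~1–2.5%, inside its 3% contract.
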