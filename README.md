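# hexstim

Finite-element simulation of transcranial direct and alternating current
stimulation (tDCS/tACS) on layered-sphere head phantoms.

Weak scalp currents (~1 mA) are increasingly used to modulate cortical
excitability, but where the current actually goes is far from obvious: most
of it is shunted through the well-conducting scalp and cerebrospinal fluid,
and what reaches the brain depends strongly on electrode placement and
tissue conductivities. `hexstim` is for researchers who want a transparent,
fully testable forward model of that current flow: it solves the
quasistatic potential problem

    ∇·(σ∇Φ) = 0,   (σ∇Φ)·n̂ = j_n on the electrode surfaces,

on a geometry-adapted hexahedral mesh with a 3×3 conductivity tensor σ per
element, computes the current density **J** = −σ∇Φ and electric field
**E** = **J**/σ, and compares electrode montages by intensity and focality.
Because individual MRI head models are not shipped, a six-compartment
layered-sphere phantom generator (skin, skull compacta/spongiosa, CSF, gray
and white matter, plus saline electrode patches at 10–20-analog positions)
stands in for a segmented head, and an analytic multi-layer sphere series
provides an independent correctness standard for the solver. See
`docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
import hexstim as hs

# phantom with electrodes at FPz (anode) and Oz (cathode), 1 mA
montage = hs.standard_montage("FPz-Oz", total_current=1e-3)
vol = hs.generate_sphere_phantom(resolution=2.0)          # 2 mm voxels
vol = hs.place_electrode_patches(vol, montage)

mesh = hs.voxels_to_hex_mesh(vol)                         # 336 536 elements
mesh = hs.geometry_adapt(mesh, vol, shift_factor=0.33)
mesh = hs.assign_conductivity(mesh)                       # 0.43/0.007/0.025/1.79/0.24/0.19 S/m

sol = hs.solve_montage(mesh, montage)                     # AMG-preconditioned CG
stats = hs.tissue_statistics(sol, mesh)
for code in (hs.Tissue.SKIN, hs.Tissue.CSF, hs.Tissue.GM):
    ts = stats[code]
    print(f"{ts.name:>5}: peak {ts.peak:.3f} A/m^2  mean {ts.mean:.3f}")
print("GM peak E-field:", round(hs.efield_magnitude(stats[hs.Tissue.GM].peak, 0.24)), "uV/mm")
```

Output:

```
 skin: peak 1.085 A/m^2  mean 0.171
  csf: peak 0.360 A/m^2  mean 0.240
   gm: peak 0.057 A/m^2  mean 0.038
GM peak E-field: 237 uV/mm
```

The ordering skin > CSF > gray matter is the shunting effect: skin and CSF
conduct far better than skull and brain, so they carry the strongest
current densities, and cortical regions adjacent to CSF receive more
current than deeper tissue. Doubling `total_current` exactly doubles every
field value (the problem is linear), and swapping anode and cathode flips
every current vector by 180° without changing magnitudes — which is also
how tACS half-waves behave (`hs.tacs_waveform_view`).

The four-montage comparison of the study configuration runs with:

```python
reports = hs.run_pipeline(hs.PipelineConfig())   # FPz-Oz, F7-F8, Cz-Oz, P7-P8
```

and shows, on the phantom, that the lateral F7/F8 pair stimulates the
frontal ROI more strongly and much more focally than the midline FPz/Oz
pair (focality fraction 0.34 vs 1.00), and that P7/P8 reaches lateral
occipital cortex better than Cz/Oz.

A `hexstim` command-line tool wraps the same functions (`hexstim phantom`,
`mesh`, `solve`, `validate`, `stats`, `compare`, `run`); see
`hexstim --help`.

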