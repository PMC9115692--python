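# stretchlab

Modeling and analysis tools for dielectric-elastomer-actuator (DEA) cell
stretchers — the "musical dish" class of device, in which a prestretched
VHB 4910 membrane carrying a transparent compliant electrode stretches
adherent cells when a high voltage squeezes the membrane through the Maxwell
stress.  Driving the voltage amplifier with a music signal produces
*nonuniform microstretching* (NUMS): sub-1% strain whose amplitude varies in
time with the music.  A constant voltage produces the matching *uniform
stretch* (US) control.  The package is aimed at mechanobiologists and soft-
robotics engineers who need to design, calibrate, or reason quantitatively
about such stimulation experiments.

## What it computes

**Electromechanics.**  The membrane is an incompressible Yeoh solid,

    W(I1) = C10 (I1 − 3) + C20 (I1 − 3)² + C30 (I1 − 3)³,

loaded electrostatically by the Maxwell stress σ_M = ε0 εr (V/t)².  For the
equibiaxially prestretched membrane (λp = 3, i.e. 200% radial prestretch)
the homogeneous equilibrium stretch solves

    σ_el(λ) = σ_el(λp) + σ_M(V, t),

with σ_el the equibiaxial Cauchy stress; `membrane_axisym` solves the full
axisymmetric field of the partially electroded, clamped membrane
(d(R·P_r)/dR = P_t with a traction-continuity jump at the electrode edge)
and quantifies the uniformity and equiaxiality of the culture zone.

**Measurement and calibration.**  Radial strain ε_r = Δr/r0 from
electrode-edge point pairs, percent linear strain, per-cycle max/min/
difference summaries of cyclic actuation traces, and OLS fitting of the
voltage–strain calibration line (default: y = 1.7 x − 0.85, % per kV).

**Transduction.**  WAV audio → amplitude-modulated voltage program
V(t) = V0 (1 + m·s(t)) → percent-strain trace via the calibration line,
plus Welch spectra and band-power summaries.

**Downstream readout.**  2^−ΔΔCt relative gene expression from qPCR Ct
tables.

**Synthetic data.**  Deterministic generators for music-like audio (most
power below 1 kHz), noisy calibration tables, drifting cyclic traces, and
Ct tables with configurable effect directions — every input the pipeline
needs, with no downloads.

## Worked example

```python
import numpy as np
from stretchlab import (
    MembraneGeometry, VHB4910, solve_actuation,
    audio_to_voltage, voltage_to_strain, strain_stats,
    gen_music_like_audio,
)

# physics: equilibrium actuating strain at 1 kV and 5 kV
geom = MembraneGeometry()          # 1 mm film, 3x prestretch
for v in (1000.0, 5000.0):
    r = solve_actuation(VHB4910, geom, v)
    print(f"{v/1000:.0f} kV -> actuating strain {100 * r.strain_act:.3f} %")

# transduction: music -> NUMS strain envelope
audio = gen_music_like_audio(duration=4.0, seed=1)
trace = voltage_to_strain(audio_to_voltage(audio, offset_kv=1.0,
                                           modulation_fraction=0.01))
lo, hi, mean, rng = strain_stats(trace)
print(f"NUMS strain envelope: {lo:.3f} .. {hi:.3f} % (mean {mean:.3f} %)")
```

prints

```
1 kV -> actuating strain 0.190 %
5 kV -> actuating strain 4.542 %
NUMS strain envelope: 0.834 .. 0.867 % (mean 0.850 %)
```

The 1 kV equilibrium strain is below 1%, the microstretch regime used for
cell stimulation; at 5 kV the elastic strain is ~4.5%, and viscoelastic
creep (see `default_drift`) carries the cyclic steady state into the
5–13% band.  A constant 1 kV maps to 0.850% strain (the US condition);
1% amplitude modulation about 1 kV maps to a ~0.833–0.867% envelope (the
NUMS condition).

A CLI mirrors these workflows:

```sh
stretchlab sweep --voltages 500,1000,2000,5000 --out sweep.csv
stretchlab axisym --voltage 5000 --nodes 400 --out field.csv
stretchlab synth music --seed 1 --out song.wav
stretchlab music2strain song.wav --offset-kv 1.0 --mod 0.01 --out nums.csv
```

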