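# nanofilm

Nanoscale domain analysis of lipid-monolayer AFM/KPFM scan images.

Mixed phospholipid films — the classic example being DOPC–DPPC, with or
without a doping cationic gemini surfactant — phase-separate into
gel-phase domains that sit a fraction of a nanometre above the fluid
matrix and carry a few hundred millivolts more surface potential.
`nanofilm` quantifies such films from paired scan images (AFM
topography in nm, Kelvin-probe surface potential in mV):

* **surface coverage** of the higher domains by two independent
  estimators — the bimodal-histogram method (threshold at the valley
  between the two phase peaks) and the particle-detection method
  (connected-component areas) — combined into a *model average* whose
  margin is the quadrature sum of the two margins;
* **domain contrasts** Δh (nm) and ΔV (mV) from many line profiles
  drawn perpendicular to domain boundaries, each reduced to
  `median(high plateau) − median(low plateau)`, aggregated into a mean
  with a Student-t 95% confidence margin;
* **electrostatic interpretation** via the Helmholtz dipole-sheet
  relation, in the field's practical units,

  $$V\,[\mathrm{mV}] = \frac{12\pi\,\mu_\perp\,[\mathrm{mD}]}{A\,[\text{Å}^2]},$$

  and the charged-sheet model $V = z\sigma/2\varepsilon_0$, which turns
  the extra potential of surfactant-doped domains into a surfactant
  number density and a surfactant-per-lipid ratio;
* a **synthetic film generator** producing ground-truthed
  topography/potential pairs (disk/polygon or coagulated morphologies,
  deposition streaks, plane tilt, tip blur on the potential channel,
  white noise), so every estimator can be validated against a known
  mask.

It is aimed at scanning-probe practitioners who want reproducible,
scriptable versions of the cross-section and histogram analyses usually
done by hand in instrument software.

## Worked example

Generate a synthetic control-like film (27% gel-phase coverage,
Δh = 0.33 nm, ΔV = 336 mV ground truth) and analyse it:

```bash
nanofilm generate --preset control --seed 1 -o out/
nanofilm analyze out/ -o report/
```

which prints

```
generated control pair in out (realized coverage 0.264)
coverage (histogram): 26.4%
coverage (particle):  26.4%
coverage (model avg): 26.4%
delta_h: 0.33 ± 0.00 nm  delta_v: 335 ± 1 mV  (n=100)
```

The coverage estimates match the generator's realized 26.4% and the
recovered contrasts sit on the ground truth within their 95% margins:
the mean of 100 boundary-crossing profiles recovers Δh = 0.33 nm and
ΔV = 335 ± 1 mV against a true 336 mV.  Full reports (CSV + JSON, with
a provenance hash of the analysis configuration) are written to
`report/`.

The same pipeline runs on your own images: `nanofilm analyze` accepts a
directory with `topography.txt` / `potential.txt` in a Gwyddion-style
whitespace-matrix dialect (optional `# pixel_size_nm:` / `# channel:`
header lines) or 32-bit float TIFF.

From Python:

```python
import nanofilm as nf

spec = nf.gs16_like_spec(seed=3)          # coagulated domains, 0.57 nm / 658 mV
truth = nf.generate_mask(spec)
topo, pot = nf.render_pair(truth)
report = nf.analyze_pair(topo, pot, nf.AnalysisConfig(spec=spec, seed=3))
print(report.delta_v)                     # (658.5..., 1.1...) mV, 95% margin
```

The lipid literature fixture and the dipole-sheet arithmetic are
available as `nanofilm table3`, which recomputes every derived cell
(dipole moments from measured potentials and vice versa) and the
DPPC−DOPC potential contrasts, and flags any mismatch.

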