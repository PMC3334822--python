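# bcmnorm

Simulation and analysis toolkit for V1 receptive-field development under
the BCM synaptic-plasticity rule and its contrast-normalized variant
(NBCM), together with the population-coding quality metrics used to
compare the two codes.

## Pipeline

1. **retina** — grayscale luminance images are log-transformed
   (photoreceptor light adaptation), convolved with a zero-DC
   difference-of-Gaussians filter (retinal ganglion cell
   center-surround, sigmas 0.75/2.25 px), edge-cropped (10 px), and cut
   into randomly placed patches that are standardized to zero mean /
   unit variance.
2. **learning** — a population of model cortical neurons learns from the
   patch stream. Each presentation computes a linear activation, an
   asymmetric tanh output (`k1·tanh(r)` for `r>0`, `k2·tanh(r)` for
   `r<0`), optionally divides by the pooled squared population activity
   (`c' = β·c / (α + Σ c²)`, the NBCM coupling), applies the BCM weight
   update `δm = η·c·(c−θ)·d`, slides the threshold
   `δθ = (c² − θ)/τ`, and anneals `η` by 0.1 % every 1000 iterations.
3. **rf_analysis** — learned weights are convolved with the same DoG (via
   zero-padded FFTs) to reconstruct stimulus-domain receptive fields;
   preferred spatial frequency / orientation and both half-maximum
   bandwidths are read off the padded amplitude spectra.
4. **metrics** — lifetime and population sparseness (Vinje–Gallant),
   dispersal, pairwise orthogonality, matrix rank at singular-value
   tolerance 2.5, and spectral coverage (encode/decode every sinusoid of
   a complete orthonormal basis through the truncated pseudo-inverse).
5. **synthetic** — 1/f random-phase image ensembles with adjustable
   vertical/horizontal orientation bias (stand-ins for natural
   photographs), rotated-ensemble controls, orthogonal-pattern streams,
   and Gabor fixtures with known ground-truth tuning.
6. **cli** — `generate` / `train` / `analyze` / `compare` orchestration.

## CLI

```sh
# synthetic image ensemble (one .npy per image + config.json)
bcmnorm generate --out runs/images --n-images 16 --size 128 --bias 2.0

# train both rules on the same synthetic statistics
bcmnorm train --out runs/bcm  --mode bcm  --seed 0
bcmnorm train --out runs/nbcm --mode nbcm --alpha 1 --beta 2 --seed 0

# coding report, tuning table, and figures from a trained state
bcmnorm analyze --state runs/nbcm/state_nbcm --out runs/nbcm/analysis

# side-by-side table
bcmnorm compare runs/bcm/analysis/coding_report.json \
                runs/nbcm/analysis/coding_report.json
```

Exit codes: 0 success, 1 usage error, 2 numerical failure. Every output
directory archives its full configuration (including seeds), so runs can
be regenerated exactly; training checkpoints carry the sampler RNG state
and resume bit-for-bit.

## Notes on conventions

- Orientation is the angle of a field's peak frequency vector, degrees
  in (−90°, 90°], with 0° meaning modulation along the horizontal axis
  (a vertical grating). Orientations are axial (mod 180°).
- Spatial frequencies are in cycles/pixel; bandwidths are full
  half-maximum extents (octaves radially, degrees along the
  iso-frequency ring), located by linear interpolation on the 4×
  zero-padded spectrum.
- Sparseness is computed on rectified (absolute) responses; dispersal is
  reported both raw (`Σσ/max σ`, in `[1, J]`) and normalized by the
  number of neurons.
- In NBCM mode the normalized response `c'` drives the weight update
  while the sliding threshold tracks the raw sigmoid output by default
  (`threshold_uses_normalized=False`); this keeps θ on the scale of the
  un-normalized responses and is the only reading that learns stably at
  η = 10⁻⁵ from uniform [−1, 1] initial weights. The alternative is a
  config switch.
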