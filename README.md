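# fuzzedge

Fuzzy-logic edge detection for smooth and noisy greyscale clinical images.

Classical derivative operators (Sobel, Prewitt, Roberts, LoG, Canny) treat
any abrupt intensity change as an edge, so impulse ("salt-and-pepper")
noise — single pixels forced to 0 or 255 — floods their output with false
edge pixels. `fuzzedge` implements a rule-based alternative aimed at
medical imagery (MRI/CT slices), where noise is common and contrast is
often weak: a 3×3 mask feeds a Mamdani fuzzy inference system whose rule
base responds to *one-sided* contrast and stays silent on *all-sided*
contrast, which is exactly the signature of an isolated impulse.

## The method

For every interior pixel `P` the eight absolute neighbourhood differences

```
ΔP_j = |P_j − P|,   j = 1..8   (P1=NW, P2=N, P3=NE, P4=W, P5=E, P6=SW, P7=S, P8=SE)
```

are fuzzified into two sets — `Lower` = trapezoid (0, 0, 25, 75) and
`Higher` = trapezoid (25, 75, 255, 255) on the grey-level universe
[0, 255]. Twelve rules of the form

```
IF ΔP1 is Higher AND ΔP2 is Higher AND ΔP8 is Lower THEN P is Edge
```

pair two `Higher` differences on one flank of the neighbourhood with a
`Lower` difference on the opposite flank (unlisted inputs are don't-care).
Rule strengths use the min t-norm; because the table holds only
Edge-consequent rules, the `NonEdge` output receives the implicit-else
strength `1 − max(rule strengths)`. Output sets are Gaussians
`NonEdge = G(m=10, d=3.5)` and `Edge = G(m=245, d=3.5)`; each is clipped at
its aggregate strength, merged pointwise by max over a 256-sample output
universe, and reduced to a crisp score by the centroid

```
c = Σ_x q_x z_x / Σ_x q_x .
```

A pixel is flagged when `c ≥ 127.5` (midpoint of the output centres). An
isolated impulse makes *every* ΔP_j `Higher`, so each rule's `Lower`
antecedent is zero, no rule fires, and the impulse scores `NonEdge` — the
mechanism of the detector's noise robustness.

For smooth, low-contrast images an optional fuzzy contrast pre-stage maps
each pixel through a three-rule system (Darker→Darkest, Grey→Grey,
Brighter→Brightest) whose centroid-defuzzified transfer function is a
monotone S-curve with mid-grey slope ≈ 1.9, stretching weak steps until the
edge rules can saturate on them.

The evaluation protocol matches the detector's intended use: noise severity
is stated as a PSNR target in dB (`PSNR = 10·log₁₀(255²/MSE)`) and realized
by bisection on the corruption density; detectors are scored by false edge
pixels (flagged on the noisy image, absent from the reference map) and by
pixel-wise sensitivity/specificity.

## Worked example

```python
import numpy as np
from scipy import ndimage
from fuzzedge import detect_edges, fixtures
from fuzzedge.evaluation import run_comparison

fix = fixtures.make_rainbow()          # 314x192, five stripes, six boundary lines
edges = detect_edges(fix.image)
_, n = ndimage.label(edges, structure=np.ones((3, 3)))
print("boundary lines:", n)

reps = run_comparison(fix.image, fix.truth, target_db=25.0,
                      detectors=["fuzzy", "sobel", "prewitt", "roberts"], seed=0)
for name, rep in reps.items():
    print(f"{name:8s} false edges: {rep.false_edges}")
```

Output:

```
boundary lines: 6
fuzzy    false edges: 8
sobel    false edges: 1913
prewitt  false edges: 1821
roberts  false edges: 1097
```

The fuzzy detector recovers all six boundary lines of the banded fixture
and, at 25 dB salt-and-pepper noise, produces two orders of magnitude fewer
false edge pixels than the gradient operators (the exact counts vary
slightly with the seed).

The same pipeline is available from the shell:

```
fuzzedge fixture rainbow -o rainbow.png --truth truth.png
fuzzedge detect rainbow.png -o edges.png
fuzzedge noise rainbow.png -o noisy.png --psnr 25 --seed 0
fuzzedge compare rainbow.png --psnr 25 --truth truth.png -o report.json
fuzzedge detect smooth.png -o edges.png --contrast     # smooth-image branch
```

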