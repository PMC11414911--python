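# mitotopo

Topological quantification of mitochondrial network morphology from 2-D
grayscale micrographs, using persistent homology over a two-parameter
filtration built from intensity thresholding and morphological opening.

Mitochondria form networks that range from interconnected tubular webs
(e.g. wild-type cells) to scattered punctate fragments (e.g. cells with
impaired fusion/mitophagy machinery). Classical image analysis quantifies
this after picking *one* intensity threshold and *one* denoising scale —
both subjective choices that change the result. `mitotopo` instead sweeps
**all** thresholds and **all** opening scales at once and reads off
topology that is stable across them.

## The model

An 8-bit image is a function `g : P → {0..255}` on a pixel grid. For a
threshold `t`, the binary image `g_t` blackens pixels with `g ≤ t`
(structure is *dark*; fluorescence images are inverted first). For the
square structuring element `S_i` of size `(i+1)×(i+1)`, the opening
`O_{S_i}` removes white regions too small to contain an all-white
`(i+1)×(i+1)` window. Both operations grow the black set monotonically, so

    X_(t,i) = K(O_{S_i}(g_t)),   t = 0..255,  i = 0..20

is a **bifiltration**: `X_(t1,i1) ⊆ X_(t2,i2)` whenever `t1 ≤ t2`,
`i1 ≤ i2`. Black pixels are closed unit squares (T-construction), so black
regions are 8-connected and enclosed white regions 4-connected; `β0`
counts components and `β1` enclosed holes. Cubical persistent homology
along each row (fixed `i`, varying `t`) and each column (fixed `t`,
varying `i`) produces diagrams `P1^{H,i}` and `P1^{V,t}`, from which three
features are derived:

| feature | definition | reads |
|---|---|---|
| normalized Betti curve | `ρ1^{H,i}(t) = β1(X_(t,i)) / #P1^{H,i}` | hole abundance vs threshold, in [0,1] |
| size distribution | `φ(D_t) = histogram(D_t)/#D_t`, `D_t = {d : (0,d) ∈ P1^{V,t}}` | granulometric hole sizes, 20 bins |
| connectivity index | `C_t = Σ_{(b,d), b>0}(d−b) / Σ_{(b,d)}(d−b)` over finite pairs of `P1^{V,t}` | share of hole lifespan created by opening; ≈1 connected, ≈0 fragmented |

Groups of images are compared by averaging `ρ` and `C_t` over thresholds
100–150 (and `φ(D_128)` over size bins 5–15) per image, then running a
two-sided permutation test on the group means, repeated over seeds
(reported as mean ± std of p-values).

## Worked example

The 3×3 image `[[1,3,2],[1,10,2],[1,3,2]]` is the package's canonical
fixture: thresholding at 1 gives the left column, at 2 two bars, at 3 an
8-pixel ring enclosing the centre, and at 10 the full square.

```bash
mitotopo synth --kind worked-example --out we.png
mitotopo diagram we.png --no-invert --out we_diagram.csv
```

prints (after the config header):

```
dim,birth,death
0,1,inf
0,2,3
1,3,10
```

— one essential component born at 1, a second component born at 2 that
merges at 3 (elder rule), and one hole born when the ring closes at 3 and
filled at 10.

A full group study runs on synthetic phantoms (connected-network vs
fragmented-punctate morphology):

```bash
for s in 0 1 2 3 4; do
  mitotopo synth --kind network    --seed $s --out wt/net$s.png
  mitotopo synth --kind fragmented --seed $s --out ko/frag$s.png
done
mitotopo compare --group-a wt --group-b ko --no-invert --seed 0 --out report.csv
```

```
feature,range,p_mean,p_std,n_A,n_B,significant
rho_0,"[100,150]",0.0092,0.0027,5,5,True
rho_3,"[100,150]",0.0092,0.0027,5,5,True
rho_5,"[100,150]",0.0092,0.0027,5,5,True
phi,"[5,15]",0.4470,0.0157,5,5,False
C,"[100,150]",0.0092,0.0027,5,5,True
```

With 5 images per group the smallest achievable two-sided p-value is
2/252 ≈ 0.0079 (add-one Monte-Carlo estimate ≈ 0.0092): the normalized
Betti curves at opening rows 3 and 5 and the connectivity index separate
the two morphology classes completely, while the size-distribution
summary does not separate these particular phantoms.

The same features are available as a scikit-learn transformer:

```python
from mitotopo import MFPHFeatureExtractor, make_network_phantom, PhantomParams
imgs = [make_network_phantom(PhantomParams(seed=s))[0].values for s in range(3)]
X = MFPHFeatureExtractor().fit(imgs).transform(imgs)   # (3, 5) feature matrix
```

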