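# cardiomorph

Automatic detection and morphometric characterization of cardiomyocytes
(CMs) in fluorescence microscopy images of cardiac tissue, with
quantification of connexin-43 (CX43) expression and its polar-vs-lateral
distribution.

Cardiomyocyte geometry and the amount and localisation of CX43 — the main
ventricular gap-junction protein, normally concentrated at the intercalated
discs at the longitudinal cell ends — are structural determinants of cardiac
electrical conduction, and CX43 *lateralization* (redistribution to the long
cell sides) is associated with arrhythmogenic remodelling.  Quantifying
these features by hand is extremely slow; this package automates the whole
chain and also scores how well the automatic detection agrees with a
manually delineated cell mask.

## Method

Input channels (8-bit grayscale, `scale` µm/pixel): `c1` cell-body marker
(SERCA2 or F-actin), `c2` CX43, `c3` interstitium (e.g. WGA; optional), and
`c4`, a duplicate of `c2` reserved for quantification.

1. **Masks.**  Each channel is optionally histogram-equalized and
   binarized (`M_ci = 1` iff `ci > thr_ci`), then cleaned by a morphological
   opening of rank `nr` and grown by `ng_it` dilations of rank `ng`
   (rank 1 = identity).  The automatic CM mask is
   `Ma = Mc1 AND NOT (Mc2 AND Mc3)`; the tissue mask is
   `Mt = Mc1 OR Mc2 OR Mc3`; the CX43 mask `Mc4` is `c2` equalized and
   thresholded at the fixed value 254 with no morphology.
2. **Cells.**  External contours of `Ma` (8-connected components, holes
   suppressed) are filtered for plausibility (area > 100 µm², perimeter
   > 40 µm), enclosed in minimum-area rotated rectangles, and padded
   outward along the box diagonals by `h = 2·ng(c2)·ng_it(c2)` pixels to
   compensate the cell-mask erosion caused by CX43-mask growth.
   Morphometry per cell: `L` (mean of fitted and padded long sides), `W`
   (fitted short side), `R = L/W`, `A = L·W`, with a second filter
   20 < L < 200 µm, 5 < W < 50 µm.
3. **CX43.**  Global expression `Cex` = % of `Mt` pixels active in `Mc4`;
   noise `r` = % of off-tissue pixels active in `Mc4`.  Each padded box is
   cut into four equal compartments along its long axis (P0/P3 polar,
   P1/P2 lateral); with `F_i` the fraction of compartment pixels carrying
   CX43, `Fp = F0+F3`, `Fl = F1+F2`, and the lateralization percentage is
   `Clat = 100·Fl/(Fl+Fp)`.  The population Clat histogram is summarised
   by fitting `f(x) = a·e^(−bx)`, whose closed-form integral
   `(a/b)(e^(−b·lo) − e^(−b·hi))` gives the fraction of cells in any
   lateralization range.
4. **Agreement.**  Manual masks pass through the same contour→box stage;
   for each manual cell the overlap with every automatic box is
   `I_ij = 100·|B_mi ∩ B_aj| / |B_mi|`, its maximum `I_i` feeds an integer
   percentile curve `Pc(k)`, and the trapezoidal area under that curve
   (AUC ∈ [0, 1]) is the agreement score.

A synthetic-scene generator renders cells with exact vector ground truth
(box, planted lateral CX43 fraction), so every stage is testable without
microscopy data.

## Worked example

Render a 5-cell synthetic scene, detect, and evaluate against the scene's
ground-truth mask:

```
$ cardiomorph synthesize --out-dir demo/scene --seed 7 --n-cells 5
wrote 5 files -> demo/scene
$ cardiomorph detect --c1 demo/scene/c1.tif --c2 demo/scene/c2.tif \
    --c3 demo/scene/c3.tif --config demo/config.yaml --out-dir demo/run
detected 5 cells -> demo/run
$ cardiomorph evaluate --manual demo/scene/manual_mask.png \
    --c1 demo/scene/c1.tif --c2 demo/scene/c2.tif --c3 demo/scene/c3.tif \
    --config demo/config.yaml --out-dir demo/eval
AUC 1.000; 5/5 manual cells matched > 50% -> demo/eval
```

(the config here is `threshold_only_config()` written to YAML — the scene
is noise-free, so no morphological cleanup is wanted).  `demo/run/cells.csv`
then contains one row per cell:

```
id,center_x_px,center_y_px,angle_deg,L_um,W_um,R,A_um2,F0,F1,F2,F3,Fp,Fl,Clat,no_signal
0,137.269,130.48,20.256,38.807,13.399,2.8962,519.98,0.0,0.12517,0.124152,0.0,0.0,0.249322,100.0,False
1,313.541,367.676,49.624,55.163,28.103,1.9629,1550.25,0.060644,0.0,0.0,0.060537,0.121181,0.0,0.0,False
...
```

Cell 0 was planted with purely lateral CX43 and is recovered with
`Clat = 100.0`; cell 1 is purely polar (`Clat = 0.0`).  The five planted
lateral fractions (100, 0, 20, 50, 80 %) are recovered as
`Clat = 100.0, 0.0, 19.9, 50.0, 80.0`, lengths/widths agree with the planted
values to sub-pixel accuracy, and the self-evaluation against the
ground-truth mask is perfect (AUC 1.0, all cells matched above 50 %
overlap).

From Python the same pipeline is three calls:

```python
from cardiomorph import random_scene, render_scene, detect_myocytes, threshold_only_config
channels, truth = render_scene(random_scene(n_cells=5, seed=7))
records = detect_myocytes(channels, threshold_only_config())
```

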