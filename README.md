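# renogray

Gray-scale median analysis of renal B-mode ultrasound images: fascia-anchored
image normalization, 14-band "virtual histology" brightness distributions,
pseudocolor rendering, and multi-operator comparability statistics — with a
synthetic speckle-phantom study generator so the whole pipeline runs with no
patient data.

## The problem

The echogenicity of the renal parenchyma is usually judged by eye against the
liver, but a display carries up to 256 shades of gray while human vision
separates perhaps 16–32 of them. Computerized gray-scale analysis quantifies a
manually segmented kidney region by its **gray-scale median**

```
GSM = median{ r_i : pixel i inside the kidney contour },   r_i ∈ [0, 255]
```

— the intensity splitting the region into a brighter and a darker half — and
by the proportional distribution of its pixels over 14 pre-established
brightness ranges, each attributed to a probable tissue type and a display
color (the "virtual histology" pseudocolor map).

Raw gray levels, however, depend on the console's gain, TGC and dynamic-range
settings, so values from different sonographers or machines are not directly
comparable. renogray implements a one-point normalization anchored on the
posterior renal fascia: with `medF0` the original GSM of a manually segmented
fascia region, the normalization factor is

```
Fn = |medF0 − 200| / medF0
```

and the transfer function applied to **every** pixel r of the image is

```
medF0 ≤ 200 :  f(r) = r (1 + Fn)
medF0 > 200 :  f(r) = r (1 − Fn)
```

i.e. the single linear map `f(r) = r · 200 / medF0`, which drives the fascia
GSM to the anchor level 200 exactly (for an odd-sized fascia region, under the
exact-factor policy). Worked example: `medF0 = 220` gives `Fn = 0.09` (two
decimals) and a pixel of 50 maps to `50 × 0.91 = 45.5 → 46`.

Whether operators then become interchangeable is tested per variable (GSM plus
the 14 band percentages) with rank-based statistics: Anderson–Darling
normality checks, the Kruskal–Wallis H test across operators and pairwise
two-sided Wilcoxon–Mann–Whitney tests, at α = 0.05, for each of the four image
categories (`random`, `standardized`, `random-normalized`,
`standardized-normalized`).

## Worked example

Generate a synthetic phantom (speckled kidney ellipse, bright posterior fascia
band), then analyze it with normalization:

```sh
python - <<'EOF'
from renogray import PhantomSpec, generate_phantom, write_gray_bmp, write_roi
spec = PhantomSpec(seed=1)              # 800x600, fascia mean 220
img, fascia, kidney = generate_phantom(spec)
write_gray_bmp(img, "phantom.bmp")
write_roi(fascia, "fascia.json"); write_roi(kidney, "kidney.json")
EOF
renogray analyze --image phantom.bmp --kidney kidney.json \
    --fascia fascia.json --normalize --out row.csv
```

prints

```
medF0=216.0 Fn=0.0741 policy=exact_factor
gsm=86.0 n=74387
```

The realized fascia GSM of this speckle draw is 216, so every pixel is scaled
by 200/216 (`Fn ≈ 0.074`); the kidney region (74 387 pixels) then has GSM 86.
`row.csv` holds the full result row — GSM, descriptive statistics and the 14
band percentages (e.g. bands 4–6, the mid-gray parenchyma ranges, hold
18.5 %, 39.9 % and 20.7 % of the region here).

A complete simulated study — 24 patients × 2 sides × 5 physicians × 2
acquisition methods = 480 images, with per-physician gain/offset biases that
apply only under the `random` method — runs with:

```sh
renogray simulate --patients 24 --seed 1 --out study/
renogray run-study --manifest study/manifest.csv --out-dir reports/
```

which writes the four-category results table (each image contributes a raw
row and a normalized row) and per-category Kruskal–Wallis and pairwise
rank-sum reports. On such a study the operator gains make the `random`
category significantly heterogeneous across physicians while the
`standardized-normalized` category shows no significant differences — the
pattern that motivates standardizing acquisition *and* normalizing images.

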