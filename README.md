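# stainmap

Pixel-wise classification of dual-chromogen-stained stem-cell micrographs
and radial (ring-wise) quantification of differentiation patterns in
circular micro-confinements.

## The problem

Human mesenchymal stem cells (hMSCs) cultured on circular adhesive islands
bounded by agarose micro-walls differentiate in a spatially patterned way:
adipogenic at the center, osteogenic toward the periphery, with a rim of
undifferentiated cells against the confining wall. After dual staining —
Oil Red O for lipid droplets (red, adipogenic) and Fast Blue for alkaline
phosphatase (blue, osteogenic) — each pixel of an RGB micrograph belongs to
one of three classes:

1. **adipogenic** (red chromogen),
2. **osteogenic** (blue chromogen),
3. **negative** (neither stain: undifferentiated cells inside the
   confinement, background outside).

The three classes form clusters near the gray diagonal of RGB space that
simple per-channel thresholding cannot separate. `stainmap` trains a
support vector machine (RBF kernel) on small labeled reference crops,
labels every pixel of whole micrographs independently from its own
(R, G, B) triple, partitions each circular confinement into coaxial rings
of fixed radial thickness (default Δr = 25 μm), and reports the per-ring
area fraction of each class, aggregated over replicate confinements as
mean ± sample SD.

Formally, with features **x** = (R, G, B)/255 ∈ [0, 1]³, the classifier is
a one-vs-one SVM: for each class pair (i, j) a decision function
f_ij(**x**) = Σ_s α_s K(**x**_s, **x**) + b_ij with RBF kernel
K(**u**, **v**) = exp(−γ‖**u**−**v**‖²); the predicted class is the vote
winner (ties broken by summed margin, then lowest class code). For a
confinement of radius R, ring k covers radii [kΔr, (k+1)Δr) and its class
fraction is (pixels of that class in ring k) / (pixels in ring k).

A seeded synthetic colony simulator generates images with exact per-pixel
ground truth (Gaussian color clusters per class, radial three-zone or
logistic layout), so the whole pipeline is testable without microscopy
data.

Intended users: cell-biology and mechanobiology labs quantifying patterned
differentiation on micropatterned substrates, and anyone needing a simple,
reproducible trainable color segmenter for chromogenic stains.

## Worked example

```python
import stainmap as sm

# train on simulated reference crops (three classes, color SD 10)
crops = sm.simulate_training_crops(crop_size=(20, 50), noise_sd=10.0, seed=42)
model = sm.train(sm.training_set_from_crops(crops))
print(f"training accuracy: {model.training_summary['training_accuracy']:.4f} "
      f"on {model.training_summary['n_samples']} pixels")

# simulate a 200 um confinement and classify it
params = sm.ColonySimParams(seed=7, image_size=(210, 210), diameter_um=200.0,
                            noise_sd=10.0,
                            layout=sm.RadialLayout(r_adipo_um=50.0, r_osteo_um=85.0))
image, truth, geometry = sm.simulate_colony(params)
labels = model.classify(image)
print(f"pixel agreement with ground truth: {(labels == truth).mean():.4f}")

# 25 um ring profile
rings = sm.build_ring_index(geometry, labels.shape, ring_thickness_um=25.0)
profile = sm.compute_ring_fractions(labels, rings)
print(profile.to_frame()[["mid_radius_um", "pixel_count",
                          "fraction_adipogenic", "fraction_osteogenic",
                          "fraction_negative"]].round(3).to_string(index=False))
```

Output:

```
training accuracy: 1.0000 on 3000 pixels
pixel agreement with ground truth: 1.0000
 mid_radius_um  pixel_count  fraction_adipogenic  fraction_osteogenic  fraction_negative
          12.5         1976                  1.0                0.000              0.000
          37.5         5884                  1.0                0.000              0.000
          62.5         9832                  0.0                1.000              0.000
          87.5        13736                  0.0                0.365              0.635
```

The SVM separates the three simulated color clusters perfectly (training
accuracy 1.0), every pixel of the noisy colony is recovered, and the
four 25 μm rings of the 200 μm confinement show the expected layout: an
adipogenic core (rings at 12.5 and 37.5 μm), an osteogenic belt
(62.5 μm), and an outermost ring mixing osteogenic area with the
undifferentiated rim (negative fraction 0.635 beyond the 85 μm zone
boundary).

## Command line

```bash
stainmap simulate --seed 7 --out-dir sim --diameter-um 200 --size 210
stainmap simulate-crops --seed 42 --out-dir crops
stainmap train --crop crops/adipogenic_01.png adipogenic \
               --crop crops/osteogenic_01.png osteogenic \
               --crop crops/negative_01.png negative \
               --model-out model.json
stainmap classify --model model.json --out-dir out sim/colony.png
stainmap profile out/colony.labels.png --pixel-size-um 1 --diameter-um 200 \
                 --out profile.csv --plot profile.png
stainmap run --config config.yaml    # end-to-end from a YAML config
```

Models are portable JSON documents; label maps are indexed PNGs whose
pixel values are the class codes; profiles are CSVs carrying both radial
coordinates (distance from center and distance from the confining wall).

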