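# dnaga-ksvm

Benign/malignant classification of 2-D grayscale brain-MRI slices, for
researchers studying entropy-based texture features and evolutionary
hyperparameter search on medical images.

The pipeline:

1. **Wavelet decomposition.** Each slice is resized to 128×128 and
   decomposed with a 3-level decimated 2-D Haar transform (orthonormal
   filters, symmetric boundary extension), giving a 16×16 approximation
   band and nine detail bands (HL/LH/HH at three scales).
2. **Tsallis-entropy features.** Every sub-band is reduced to the Tsallis
   entropy S_q = (1 − Σᵢ pᵢ^q)/(q − 1) of its 256-bin gray-level
   histogram, yielding a 10-dimensional feature vector. The non-extensive
   parameter q weights rare versus dominant gray levels and recovers the
   Shannon entropy −Σᵢ pᵢ ln pᵢ as q → 1.
3. **Kernel SVM.** A soft-margin SVM with the Gaussian kernel
   K(x, y) = exp(−σ‖x − y‖²) (σ is a gamma-style multiplier) separates the
   classes; features are standardized with training-set statistics.
4. **DNA genetic algorithm.** The triple (q, C, σ) — entropy parameter,
   slack penalty, kernel width — is tuned by a genetic algorithm over
   base-4 "nucleotide" chromosomes (C=0, T=1, A=2, G=3; 8 digits per
   parameter), with elitist tournament selection, three segment-level
   crossover operators (transformation, permutation, translocation) and
   four single-base mutation operators (reversal, transition, exchange,
   point). The fitness of a chromosome is the mean held-out accuracy of
   stratified five-fold cross-validation at its decoded parameters.

A phantom generator stands in for clinical archives: concentric-ellipse
slices with CSF/GM/WM bands in T2-like contrast, optional hyperintense
lesions defining the malignant class, and Rician noise
√((I + n₁)² + n₂²) at a requested SNR.

## Worked example

```python
from dnaga_ksvm import DnagaKsvmClassifier, WIDE_Q_SPECS, make_dataset

# 90 phantoms (45 benign, 45 malignant) at 10 dB Rician noise
images, labels, _ = make_dataset(45, 45, snr_db=10.0, seed=1)

clf = DnagaKsvmClassifier(param_specs=WIDE_Q_SPECS, population_size=20,
                          max_generations=10, random_state=0)
clf.fit(images, labels)
print(f"q* = {clf.q_:.3f}, C* = {clf.C_:.1f}, sigma* = {clf.sigma_:.3f}")
print(f"five-fold CV fitness = {clf.cv_fitness_:.4f}")
cm = clf.cv_confusion(labels)
print(f"held-out confusion: TP={cm.tp} FP={cm.fp} FN={cm.fn} TN={cm.tn}")
print(f"sensitivity = {cm.sensitivity_pct}%, specificity = {cm.specificity_pct}%, "
      f"accuracy = {cm.accuracy_pct}%")
```

prints

```
q* = 1.808, C* = 144.5, sigma* = 0.567
five-fold CV fitness = 0.9444
held-out confusion: TP=44 FP=4 FN=1 TN=41
sensitivity = 97.78%, specificity = 91.11%, accuracy = 94.44%
```

The genetic search settles on a q above 1 for this dataset, a moderate
slack penalty and a fairly local kernel; at 10 dB the tuned pipeline
recovers the planted lesion contrast on 85 of 90 held-out predictions
(one malignant slice missed, four benign slices over-called). At 20 dB the
same configuration reaches a CV fitness of 1.0; at 5 dB it degrades toward
~0.85.

`DnagaKsvmClassifier` follows the scikit-learn estimator protocol
(`get_params`/`set_params`, fitted attributes `q_`, `C_`, `sigma_`,
`cv_fitness_`, `model_`, `history_`), and `TsallisWaveletFeaturizer` is a
standalone transformer producing the 10 entropy features at a fixed q.

## Command line

```sh
dnaga-ksvm simulate --preset aanlib --out data/        # 90-image phantom set
dnaga-ksvm train data/manifest.csv --out run/          # model.json, history.csv, metrics.csv
dnaga-ksvm classify run/model.json data/img_0001.png --out pred.csv
dnaga-ksvm evaluate pred.csv data/manifest.csv --out eval.csv
```

All commands accept `--config <json>` (flags override file values),
`--seed`, and `--show-config`.

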