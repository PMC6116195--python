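"""Extract the 57-feature texture signature of one synthetic tumor.

The signature averages each of the 19 Haralick quantifiers over a bank of
co-occurrence matrices (5 quantization levels x 4 distances x 4 angles) and
does so for three matrix families: GLCM of the T2-weighted ROI, GLCM of the
ADC ROI, and the cross-modality JIM (T2 rows, ADC columns).
"""

from jimrad import PhantomParams, generate_pair, histogram_features, tumor_signature

t2, adc = generate_pair(PhantomParams(shape=(21, 21, 10), rho=0.6, seed=11))

signature = tumor_signature(t2, adc)
print(f"texture features: {len(signature)}")
for name in (
    "GLCM_T2_contrast",
    "GLCM_ADC_contrast",
    "JIM_contrast",
    "JIM_difference_variance",
    "JIM_homogeneity",
):
    print(f"  {name:28s} {signature[name]:10.4f}")

hist = histogram_features(t2)
print(f"first-order histogram features of the T2 ROI ({len(hist)}):")
for name, value in hist.items():
    print(f"  {name:28s} {value:10.4f}")
# Contrast and difference variance grow with fine-grained texture; the JIM
# versions also respond to how tightly the two modalities are coupled.
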