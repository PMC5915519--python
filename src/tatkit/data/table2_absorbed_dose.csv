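# description: Published absorbed-dose coefficients of 211At-MABG (Gy per MBq injected), used as an external reference for comparison, not produced by this package.
organ,dose_gy_per_mbq
Blood,0.18
Liver,1.41
Kidney,0.61
Adrenals,5.07
Intestine,1.45
Spleen,2.32
Pancreas,1.28
Stomach,1.46
Heart,4.08
Lung,1.63
Thyroid,1.49
Muscle,0.52
Bone,0.47
Brain,0.02
PC12 tumor,10.21
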