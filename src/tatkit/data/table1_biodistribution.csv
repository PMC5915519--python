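# decay_corrected: true
# description: Biodistribution of 211At-MABG in PC12 tumor-bearing mice (mean +/- SD, n=5 per time point). Units are %ID/g except thyroid (%ID, whole organ).
organ,unit,time_h,mean,sd,n
Blood,per_gram,1,0.83,0.05,5
Blood,per_gram,3,0.53,0.04,5
Blood,per_gram,6,0.41,0.04,5
Blood,per_gram,12,0.39,0.07,5
Blood,per_gram,24,0.25,0.07,5
Liver,per_gram,1,9.79,1.44,5
Liver,per_gram,3,5.30,0.57,5
Liver,per_gram,6,3.17,0.30,5
Liver,per_gram,12,2.22,0.34,5
Liver,per_gram,24,1.05,0.32,5
Kidney,per_gram,1,2.88,0.23,5
Kidney,per_gram,3,1.83,0.06,5
Kidney,per_gram,6,1.65,0.19,5
Kidney,per_gram,12,1.24,0.30,5
Kidney,per_gram,24,0.77,0.15,5
Adrenals,per_gram,1,14.51,4.32,5
Adrenals,per_gram,3,10.71,2.96,5
Adrenals,per_gram,6,20.77,8.22,5
Adrenals,per_gram,12,9.11,2.60,5
Adrenals,per_gram,24,10.43,1.59,5
Intestine,per_gram,1,7.18,0.73,5
Intestine,per_gram,3,4.32,0.22,5
Intestine,per_gram,6,3.99,0.69,5
Intestine,per_gram,12,2.93,0.91,5
Intestine,per_gram,24,1.74,0.50,5
Spleen,per_gram,1,6.82,1.23,5
Spleen,per_gram,3,6.27,0.85,5
Spleen,per_gram,6,6.42,0.82,5
Spleen,per_gram,12,4.43,0.93,5
Spleen,per_gram,24,3.08,0.87,5
Pancreas,per_gram,1,7.62,0.86,5
Pancreas,per_gram,3,3.89,0.84,5
Pancreas,per_gram,6,2.22,0.49,5
Pancreas,per_gram,12,1.68,0.45,5
Pancreas,per_gram,24,0.95,0.21,5
Stomach,per_gram,1,3.41,1.04,5
Stomach,per_gram,3,2.41,0.44,5
Stomach,per_gram,6,5.08,1.08,5
Stomach,per_gram,12,6.71,0.76,5
Stomach,per_gram,24,3.39,1.10,5
Heart,per_gram,1,18.49,1.54,5
Heart,per_gram,3,11.61,2.99,5
Heart,per_gram,6,7.35,1.89,5
Heart,per_gram,12,4.94,1.56,5
Heart,per_gram,24,2.66,0.32,5
Lung,per_gram,1,8.49,2.00,5
Lung,per_gram,3,4.57,1.21,5
Lung,per_gram,6,2.68,1.22,5
Lung,per_gram,12,2.67,0.63,5
Lung,per_gram,24,1.64,0.77,5
Muscle,per_gram,1,2.15,0.14,5
Muscle,per_gram,3,1.59,0.28,5
Muscle,per_gram,6,1.20,0.17,5
Muscle,per_gram,12,0.88,0.21,5
Muscle,per_gram,24,0.42,0.17,5
Bone,per_gram,1,2.24,0.42,5
Bone,per_gram,3,1.20,0.20,5
Bone,per_gram,6,0.86,0.27,5
Bone,per_gram,12,0.74,0.10,5
Bone,per_gram,24,0.38,0.27,5
Brain,per_gram,1,0.13,0.04,5
Brain,per_gram,3,0.08,0.01,5
Brain,per_gram,6,0.04,0.01,5
Brain,per_gram,12,0.07,0.03,5
Brain,per_gram,24,0.03,0.01,5
PC12 tumor,per_gram,1,29.10,9.31,5
PC12 tumor,per_gram,3,36.21,16.74,5
PC12 tumor,per_gram,6,22.85,10.69,5
PC12 tumor,per_gram,12,28.39,14.94,5
PC12 tumor,per_gram,24,16.43,5.69,5
Thyroid,per_organ,1,1.52,0.94,5
Thyroid,per_organ,3,1.65,0.97,5
Thyroid,per_organ,6,0.72,0.47,5
Thyroid,per_organ,12,0.61,0.40,5
Thyroid,per_organ,24,0.61,0.19,5
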