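compound,r1,r2,r3,pic50_exp,pic50_mlr,pic50_gapls
4a,C6H5CH2,C6H5CO,OCH3,4.17,4.01,3.90
4b,C6H5CH2,p-CH3C6H4CO,OCH3,4.08,3.82,3.92
4c,C6H5CH2,CH3CO,OCH3,4.56,4.42,4.61
4d,C6H5CH2,CH3SO2,OCH3,4.75,4.74,4.74
4e,C6H5CH2,p-CH3C6H4SO2,OCH3,4.97,4.75,4.86
4f,C6H5CH2CH2,C6H5CO,OCH3,4.13,4.16,3.79
4g,C6H5CH2CH2,p-CH3C6H4CO,OCH3,4.07,3.94,4.42
4h,C6H5CH2CH2,CH3CO,OCH3,4.90,4.98,4.97
4i,C6H5CH2CH2,CH3SO2,OCH3,5.62,5.82,5.98
4j,C6H5CH2CH2,p-CH3C6H4SO2,OCH3,5.20,5.24,5.44
5a,C6H5CH2,C6H5CO,OH,5.01,4.39,4.78
5b,C6H5CH2,p-CH3C6H4CO,OH,5.09,4.77,4.30
5c,C6H5CH2,CH3CO,OH,5.52,5.68,5.66
5d,C6H5CH2,CH3SO2,OH,5.85,6.03,6.06
5e,C6H5CH2,p-CH3C6H4SO2,OH,5.60,5.99,5.91
5f,C6H5CH2CH2,C6H5CO,OH,5.12,5.57,5.33
5g,C6H5CH2CH2,p-CH3C6H4CO,OH,5.35,5.90,5.82
5h,C6H5CH2CH2,CH3CO,OH,6.12,6.67,6.08
5i,C6H5CH2CH2,CH3SO2,OH,6.92,6.69,6.48
5j,C6H5CH2CH2,p-CH3C6H4SO2,OH,6.57,6.49,6.52
6a,C6H5CH2,C6H5CO,NHOH,5.77,6.04,5.84
6b,C6H5CH2,p-CH3C6H4CO,NHOH,6.34,6.42,6.82
6c,C6H5CH2,CH3CO,NHOH,7.43,7.32,6.84
6d,C6H5CH2,CH3SO2,NHOH,7.17,7.44,7.39
6e,C6H5CH2,p-CH3C6H4SO2,NHOH,7.60,7.19,7.14
6f,C6H5CH2CH2,C6H5CO,NHOH,6.05,6.05,6.86
6g,C6H5CH2CH2,p-CH3C6H4CO,NHOH,5.41,5.57,5.95
6h,C6H5CH2CH2,CH3CO,NHOH,7.89,7.55,7.53
6i,C6H5CH2CH2,CH3SO2,NHOH,7.54,7.91,7.94
6j,C6H5CH2CH2,p-CH3C6H4SO2,NHOH,7.77,7.49,7.73
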