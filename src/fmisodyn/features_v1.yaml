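version: 1
features:
- suv_max
- suv_mean
- suv_variance
- suv_skewness
- suv_kurtosis
- hist_entropy
- hist_uniformity
- volume_ml
- sphericity
- major_axis_mm
- glcm_energy
- glcm_contrast
- glcm_entropy
- glcm_homogeneity
- glcm_correlation
- glcm_sum_average
- glcm_variance
- glcm_dissimilarity
- glcm_autocorrelation
- glrlm_sre
- glrlm_lre
- glrlm_gln
- glrlm_rln
- glrlm_rp
- glrlm_lgre
- glrlm_hgre
- glrlm_srlge
- glrlm_srhge
- glrlm_lrlge
- glrlm_lrhge
- glrlm_glv
- glrlm_rlv
- glszm_sze
- glszm_lze
- glszm_gln
- glszm_zsn
- glszm_zp
- glszm_lgze
- glszm_hgze
- glszm_szlge
- glszm_szhge
- glszm_lzlge
- glszm_lzhge
- glszm_glv
- glszm_zsv
- ngtdm_coarseness
- ngtdm_contrast
- ngtdm_busyness
- ngtdm_complexity
- ngtdm_strength
- wf_glcm_energy
- wf_glcm_contrast
- wf_glcm_entropy
- wf_glcm_homogeneity
- wf_glcm_correlation
- wf_glcm_sum_average
- wf_glcm_variance
- wf_glcm_dissimilarity
- wf_glcm_autocorrelation
- wf_glrlm_sre
- wf_glrlm_lre
- wf_glrlm_gln
- wf_glrlm_rln
- wf_glrlm_rp
- wf_glrlm_lgre
- wf_glrlm_hgre
- wf_glrlm_srlge
- wf_glrlm_srhge
- wf_glrlm_lrlge
- wf_glrlm_lrhge
- wf_glrlm_glv
- wf_glrlm_rlv
- wf_glszm_sze
- wf_glszm_lze
- wf_glszm_gln
- wf_glszm_zsn
- wf_glszm_zp
- wf_glszm_lgze
- wf_glszm_hgze
- wf_glszm_szlge
- wf_glszm_szhge
- wf_glszm_lzlge
- wf_glszm_lzhge
- wf_glszm_glv
- wf_glszm_zsv
- wf_ngtdm_coarseness
- wf_ngtdm_contrast
- wf_ngtdm_busyness
- wf_ngtdm_complexity
- wf_ngtdm_strength
- q_glcm_energy
- q_glcm_contrast
- q_glcm_entropy
- q_glcm_homogeneity
- q_glcm_correlation
- q_glcm_sum_average
- q_glcm_variance
- q_glcm_dissimilarity
- q_glcm_autocorrelation
- q_glrlm_sre
- q_glrlm_lre
- q_glrlm_gln
- q_glrlm_rln
- q_glrlm_rp
- q_glrlm_lgre
- q_glrlm_hgre
- q_glrlm_srlge
- q_glrlm_srhge
- q_glrlm_lrlge
- q_glrlm_lrhge
- q_glrlm_glv
- q_glrlm_rlv
- q_glszm_sze
- q_glszm_lze
- q_glszm_gln
- q_glszm_zsn
- q_glszm_zp
- q_glszm_lgze
- q_glszm_hgze
- q_glszm_szlge
- q_glszm_szhge
- q_glszm_lzlge
- q_glszm_lzhge
- q_glszm_glv
- q_glszm_zsv
- q_ngtdm_coarseness
- q_ngtdm_contrast
- q_ngtdm_busyness
- q_ngtdm_complexity
- q_ngtdm_strength
aliases:
  LGZE: glszm_lgze
  C_CM: glcm_correlation
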