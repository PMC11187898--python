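name,a,b,c,alpha,beta,gamma,laue_group,density,source
L-Glutamic acid,5.17,6.95,17.30,90,90,90,mmm,1.54,synthetic CSD-style reference cell
L-Alanine,5.78,6.03,12.34,90,90,90,mmm,1.40,synthetic CSD-style reference cell
L-Tyrosine,6.91,21.12,5.83,90,90,90,mmm,1.41,synthetic CSD-style reference cell
L-Serine,8.58,9.20,5.60,90,90,90,mmm,1.54,synthetic CSD-style reference cell
L-Valine,9.71,5.27,12.06,90,90.8,90,2/m,1.23,synthetic CSD-style reference cell
L-Cysteine,8.12,12.18,5.42,90,90,90,mmm,1.50,synthetic CSD-style reference cell
L-Threonine,13.61,7.74,5.14,90,90,90,mmm,1.46,synthetic CSD-style reference cell
L-Aspartic acid,7.62,6.98,5.14,90,99.8,90,2/m,1.66,synthetic CSD-style reference cell
L-Glutamine,16.02,7.76,5.10,90,90,90,mmm,1.47,synthetic CSD-style reference cell
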