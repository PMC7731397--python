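# Published 48-feature reference selection for an LDA watermelon-seed
# viability model (SFS + Fisher score, whole-seed ROI).  One name per line;
# [Max-X]/[sd-X] block tags identify the enhancement set in their suffix.
i-Gabor(1,1)[Max-A]
i-LBP(3,34)[8,u2][sd-C]
i-LBP(2,53)[8,u2][sd-B]
Fourier Ang (2,1)[rad][Max-C]
i-LBP(3,44)[8,u2][sd-A]
Fourier Abs (1,1)[Max-C]
i-Gabor-J[sd-A]
i-LBP(3,27)[8,u2][sd-A]
i-LBP(3,58)[8,u2][Max-A]
i-LBP(1,10)[8,u2][Max-C]
i-LBP(4,57)[8,u2][sd-C]
i-LBP(3,56)[8,u2][Max-C]
i-LBP(1,52)[8,u2][sd-C]
i-LBP(1,38)[8,u2][sd-A]
i-LBP(1,46)[8,u2][sd-C]
i-LBP(3,12)[8,u2][sd-C]
i-LBP(3,2)[8,u2][Max-A]
i-LBP(2,30)[8,u2][sd-A]
i-LBP(2,46)[8,u2][sd-A]
i-LBP(4,13)[8,u2][sd-B]
i-LBP(2,20)[8,u2][sd-B]
i-LBP(2,20)[8,u2][sd-A]
i-LBP(2,48)[8,u2][sd-C]
i-LBP(1,29)[8,u2][sd-B]
i-LBP(2,2)[8,u2][sd-C]
i-LBP(2,26)[8,u2][sd-A]
i-LBP(2,29)[8,u2][Max-B]
i-LBP(1,36)[8,u2][sd-C]
i-LBP(4,42)[8,u2][sd-A]
i-LBP(3,51)[8,u2][sd-C]
i-LBP(2,6)[8,u2][sd-A]
i-Intensity Skewness[Max-C]
i-LBP(3,2)[8,u2][sd-C]
i-LBP(3,41)[8,u2][Max-C]
i-LBP(1,57)[8,u2][Max-A]
i-LBP(1,5)[8,u2][Max-A]
i-LBP(1,30)[8,u2][sd-B]
i-LBP(1,51)[8,u2][Max-A]
i-LBP(2,57)[8,u2][Max-B]
Fourier Ang (2,2)[rad][Max-C]
i-LBP(3,15)[8,u2][Max-A]
i-LBP(1,37)[8,u2][sd-A]
i-LBP(1,50)[8,u2][sd-B]
i-LBP(4,21)[8,u2][sd-C]
i-LBP(2,35)[8,u2][sd-A]
i-LBP(1,8)[8,u2][Max-C]
i-LBP(3,34)[8,u2][sd-B]
i-LBP(3,7)[8,u2][sd-B]
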