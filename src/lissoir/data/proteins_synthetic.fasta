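>CO1A1_BOVIN_SYNTH synthetic stand-in fragment of bovine collagen alpha-1(I)
GVQGPPGPAGPRGEAGPSGPAGPTGARGLPGESGAVGPAGPIGSRGFSGLDGAK
>CO1A2_BOVIN_SYNTH synthetic stand-in fragment of bovine collagen alpha-2(I)
GIPGPVGAAGATGARGPSGPQGIRGVVGLPGQR
>CO1A1_HUMAN_SYNTH synthetic stand-in fragment of human collagen alpha-1(I)
GETGPAGPAGPIGPVGARGANGAPGIAGAPGFPGAR
>TRYP_PIG_SYNTH synthetic stand-in fragment of porcine trypsin
VATVSLPRLSSPATLNSRIITHPNFNGNTLDNDIMLIK
>K2C1_HUMAN_SYNTH synthetic stand-in fragment of human keratin 1
SLDLDSIIAEVKTHNLEPYFESFINNLRFLEQQNQVLQTK
>K1C10_HUMAN_SYNTH synthetic stand-in fragment of human keratin 10
LENEIQTYRSQYEQLAEQNRNVQALEIELQSQLALK
>K2C1_BOVIN_SYNTH synthetic stand-in fragment of bovine keratin 1
TLDLDGIIAEVKAHNLEPYFETFINNLRFLEQQNKVLETK
>K1C10_BOVIN_SYNTH synthetic stand-in fragment of bovine keratin 10
LDNEIQTYRSQYEELAEQNRKDAEAWFNEK
>ALBU_BOVIN_SYNTH synthetic stand-in fragment of bovine serum albumin
LVNELTEFAKAEFVEVTKYLYEIAR
>HBA_BOVIN_SYNTH synthetic stand-in fragment of bovine hemoglobin alpha
VGGHAAEYGAEALERMFLSFPTTK
>HBB_BOVIN_SYNTH synthetic stand-in fragment of bovine hemoglobin beta
VNVDEVGGEALGRLLVVYPWTQR
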