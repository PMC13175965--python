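variant	canonical
NIVOLUMAB	nivolumab
OPDIVO	nivolumab
PEMBROLIZUMAB	pembrolizumab
KEYTRUDA	pembrolizumab
CEMIPLIMAB	cemiplimab
CEMIPLIMAB-RWLC	cemiplimab
LIBTAYO	cemiplimab
ATEZOLIZUMAB	atezolizumab
TECENTRIQ	atezolizumab
AVELUMAB	avelumab
BAVENCIO	avelumab
DURVALUMAB	durvalumab
IMFINZI	durvalumab
IPILIMUMAB	ipilimumab
YERVOY	ipilimumab
TREMELIMUMAB	tremelimumab
TREMELIMUMAB-ACTL	tremelimumab
IMJUDO	tremelimumab
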