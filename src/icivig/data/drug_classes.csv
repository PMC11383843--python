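standardized_name,class
nivolumab,PD1
pembrolizumab,PD1
cemiplimab,PD1
sintilimab,PD1
atezolizumab,PDL1
durvalumab,PDL1
avelumab,PDL1
ipilimumab,CTLA4
tremelimumab,CTLA4
temozolomide,CHEMO
lomustine,CHEMO
carmustine,CHEMO
carboplatin,CHEMO
cisplatin,CHEMO
vincristine,CHEMO
cyclophosphamide,CHEMO
etoposide,CHEMO
irinotecan,CHEMO
procarbazine,CHEMO
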