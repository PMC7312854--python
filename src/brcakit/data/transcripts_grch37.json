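{
  "BRCA1": {
    "gene_symbol": "BRCA1",
    "transcript_id": "NM_007294.3",
    "chrom": "17",
    "strand": "-",
    "cds_g_start": 41197695,
    "cds_g_end": 41276113,
    "exons": [
      [41196312, 41197819],
      [41199660, 41199720],
      [41201138, 41201211],
      [41203080, 41203134],
      [41209069, 41209152],
      [41215350, 41215390],
      [41215891, 41215968],
      [41219625, 41219712],
      [41222945, 41223255],
      [41226348, 41226538],
      [41228505, 41228631],
      [41234421, 41234592],
      [41242961, 41243049],
      [41243452, 41246877],
      [41247863, 41247939],
      [41249261, 41249306],
      [41251792, 41251897],
      [41256139, 41256278],
      [41256885, 41256973],
      [41258473, 41258550],
      [41267743, 41267796],
      [41276034, 41276132],
      [41277288, 41277500]
    ]
  },
  "BRCA2": {
    "gene_symbol": "BRCA2",
    "transcript_id": "NM_000059.3",
    "chrom": "13",
    "strand": "+",
    "cds_g_start": 32890598,
    "cds_g_end": 32972907,
    "exons": [
      [32889617, 32889804],
      [32890559, 32890664],
      [32893214, 32893462],
      [32899213, 32899321],
      [32900238, 32900287],
      [32900379, 32900419],
      [32900636, 32900750],
      [32903580, 32903629],
      [32905056, 32905167],
      [32906409, 32907524],
      [32910402, 32915333],
      [32918695, 32918790],
      [32920964, 32921033],
      [32928998, 32929425],
      [32930565, 32930746],
      [32931879, 32932066],
      [32936660, 32936830],
      [32937316, 32937670],
      [32944539, 32944694],
      [32945093, 32945237],
      [32950807, 32950928],
      [32953454, 32953652],
      [32953887, 32954050],
      [32954144, 32954282],
      [32968826, 32969070],
      [32971035, 32971181],
      [32972299, 32973809]
    ]
  }
}
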