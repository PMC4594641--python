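       27
       98       120
       36        89       198
      240        23        65        41
       26        72        18       250       409
      371         0        24       208        32         0
       23       246         1         9       240        64        15
      464        90        14       103       154        26       201         8
       24       905         0       103       148       139       535        77        34
      318         1        14        42       495       229        23        95        15         0
      134      1153       125        86        24         0        71         0         0        13        95
       66         0         0        18         0         0        11        28        44         0         0         0
        0        19       161        16         0        96        49       716        28       606        18        73       153
      114         0       153        56        53         0         0        35        81        43        61        11        83        30
        0        51        79        34         0        22        37        10         0         7        27        17        15        34       234
       30         0         0        54         7        44        26         0        48        94        35        22        27       127        44       257
       46       336       196        12        24       192         0        37       889        18       527       157        32        17        33        46        28
      175       243         0        33        96       136         0        13        10        92        17        62       104         0         0       258        11        46
       13        76       698        12       245        78         0         0        48       550        75        34        30         0        42       157        61         0        28

0.087126913 0.040903959 0.04043196 0.046871953 0.033473967 0.038254962 0.04952995 0.088611911 0.033617966 0.036885963 0.085356915 0.08048192 0.014752985 0.03977196 0.050679949 0.06957693 0.058541941 0.01049399 0.02991597 0.064717935
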