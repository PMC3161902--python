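protein_id	compartment	sequence	declared_length
AcoTrz2	C	MKISLGISTSPILLPFSKPTLKIPHNRVCIP	31
AlyTrz2	C	MQLSSFPISPSKIFPFTKYHAPPVIIHQLAAQIQSHRSNFVSPVKVSGYFSSISRAIEEEEEYRKAR	67
AthTrz2	C	MQLSSSFPISPPKIFPSTKHHKPPVITHQLAAQIQSNRRHFVSPVKVSGYFSSISRAIEEEEEYRKAR	68
BdiTrz2	C	MATISLFSLPPLRLTRGLLSPSSGPASRFQTL	32
CpaTrz2	C	MLTSVPILPSKLQSVFPFGHHHYHSISHKPTPIHQFSFLV	40
CclTrz2	C	MQLSLPTSPSKLPTIFPFHPSSIPKTPQSPHHLSLQSHVGPLNALKSAGFLSSISRAIDEEEEYRKAR	68
CsiTrz2	C	MQLSLPTSPSKLPTIFPFHPSSIPKTPQSPHHLSLQSHVGPLNALKSAGFLSSISRAIDEEEEYRKAR	68
CsaTrz2	C	MQISIPISPLRPPQVFPFHQPLLHTPKPPGVALQSHLNPVNSFRDSGLLSTIGVE	55
EgrTrz2	C	MRISIPISPSKSPQIFPFHHHHRRRHQIPDLRRRPPALSLPASAVNPLKSSGYLSTIHR	59
GmaTrz2	C	MQISLSDLAFKTPQLFPIHHPIFPPKPPLNHQVST	35
MesTrz2	C	MQTSFPVSPSKIPSIFPFNHPILHNPTAPTNHHQLPLQTYLKRPINSTSLKSSGFLSAIGRAIEEEEEYKKAR	73
MtrTrz2	C	MQIPLTNPTFKPPQIFPFHHTIPSPKQQLSFPT	33
MguTrz2	C	MITLNPTTSNLLNLHPFHPTPATHKHHLPPQTRRSVIACVSDAVV	45
OsaTrz1	C	MANSGKSSPAATSTTAPPPGRPKAKAPPLTVEGYPVEGISIGGQETCVIFPT	52
OsaTrz2	C	MAATSLLSLPSLRLTHRLLVPASSSAPASRSQFQTL	36
PtrTrz2	C	MQISIPL	7
PpeTrz2	C	MQIFLTISPCKAPLILPFHPPISKTPKTQRTSLKTLSKPYRLARSQVLRKGV	52
RcoTrz2	C	MQTSLPISHSKFPSIFPFNHPISHKPTTTR	30
SitTrz2	C	MATASLFSPPSLRLLSRTTARLSRFQTLAARKPP	34
SbiTrz2	C	MATASLFSLPSLRALSRTSARCSRFQTLAARKPVESSSSTATS	43
VviTrz2	C	MQISLPFSTSKVPYLSPLPNPTPQPPLTIPKPHPKSYIT	39
ZmaTrz2	C	MVTASLFSLPSLRVLSRTSAHGPRFQILAARKPVESSTATSGSRRGGSKGAGLLSVLDR	59
AcoTrz4	M	MPQISSNLKLFFSKTNHSPLFQFSFKASFCSSFLLSSKTPYKPLSSVTVISSSSSSSSSSRKGPKFPPLRSRS	73
AlyTrz3	M	MINSMPYLHKNLRLLLLLSSKSSPFPLSLRPFSPRSFSLSTLFS	44
AlyTrz4	M	MLTSSMPHRHVPQNLSLFGFSPLKSSSFALFLRPFSLYPPIFASSSPSPSRRPPRTAGYRRS	62
AthTrz3	M	MINSMPYLHKNLRLLRLLSSKSSPFPLSLRPFSPRSFSLSTLFS	44
AthTrz4	M	MLTSSMPQNLSLFGFSPLKSSSFALILRPFSLYPPIFASSSPAPSRRPPRTAGYRRSGPSPPRRK	65
BdiTrz3	M	MPQVAAPLRLLLPLSQTLAPPAPLLHLSRRLLSFCSPASFRRAASLRALAYRRSRHPEPRRG	62
CpaTrz3	M	MFLIYPNLRLLLNPPLFLFSKPNSTPLSLFTVFASSSHKRHRSVSYRDSPFGLHRRRRNFTTFKERD	67
CclTrz3	M	MPFITPNLRLLFSSSSSSLFPLKLSVPLLSTKPTNRHRSLFTILSYSKRQRSTPFPQQNQRRN	63
CsiTrz3	M	MPFITPNLRLLFSSSSSSSLFPLKLSVPLLSTKPTNRHHSLFTILSYSKRQRSTPFPQQNQRRN	64
CsaTrz3	M	MPLPHLSTLRFLFFSPSKLPFSPSLYSPKSHSLFTVLASSPPKRRRSATAPPSLNFKRRN	60
EgrTrz3	M	MPCVYSNLRLLFSSSATAAAATATAAASPFLSPLKLKLRRPSSSSSAFPLLPLPPLSSLRS	61
GmaTrz3	M	MAQVSKFGYFLLHSSLPKPSNIQFRSLLTVLASSSKRHRRK	41
GmaTrz4	M	MAQVSKFGHLLLHSSLPKPSNSNIQFRSLLTLLASSSKRHRSIPPFRRKS	50
MesTrz3	M	MPQISNLRFLLSPIKPSLPFPFSKPKPYSLFTVLCSSSSSRRHRTTPNHQSLNFRSRS	58
MesTrz4	M	MPNVLNFKLCLSDLLTQCCKICLQHYILTFSSLSHVLVSGKLQSSNPQTYFSINNPLPRSKNSRT	65
MtrTrz3	M	MAQILNFRNFLFLPSYKPTTHFRLRFLSTLVSSSSRRSNINAPPLHLRRRS	51
MguTrz3	M	MPQSTNLRLLLSSANCHRRHPFSAASNFFPKHLSFSSSFQFFLKPQFKTREIPLLFATFSSYSKKPYATNNNSNNNNKNSRSFNRN	86
OsaTrz3	M	MPQLPSPLRRLLPLSQTLAAATPAPLLHLSRRLFSSSSSPSPSPSPRAACLRALAYRGGQAGGGGRRGHHNNLLRRG	77
PtrTrz3	M	MSHISNLRLLLSPLNPTLRFPFSSKHRPYSLLTILSSSSPYPKRRHRTTPNHPSLNFRSRS	61
PpeTrz3	M	MPQVTNLRLLFFSPFPRLSLSSLSFKPLKPRTLFTALASSYRKRHRPIPNQSPNTGARN	59
SitTrz5	M	MPQVAAPLRLLLPLSQTLAPAPLLHLSRRLFTSSSPSFGRAASLRALAYRRHHHPRRGSSTLRK	64
SbiTrz4	M	MPQVAGPLRRLLPLSQTLASAPAPLLHLSRRLLSSCSPASFGRAASLRALAYRRRRHPEPRRG	63
VviTrz3	M	MPHLTSFRLLYCSPLLSPFKSPFLSFSTLSKSKSPLLNPPSFFTVLSSSSGRYPKLRRHPHHLRRRN	67
ZmaTrz3	M	MPQVAAPLRLLLPLSQTLAAPAPLLHHSRRLLSSCPASLSRAAGLRALAYRRRRHTEPRRG	61
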